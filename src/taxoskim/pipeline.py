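"""End-to-end orchestration of the skimming workflow.

Stage order mirrors the field workflow: ``qc`` → ``mine-loci`` →
``consensus`` → ``place`` → ``map-genome`` → ``classify`` →
``depth-benchmark``. Each stage writes its tables into the run directory
and contributes a block to ``report.json``; a single global seed
deterministically derives per-stage seeds (stage-name hashing), so reruns
of the same config are byte-identical and stages can be rerun in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import community, consensus as cons, qc as qcmod, seqio
from .align import alignments_to_outfmt6, map_genome, mine_loci
from .read_model import ErrorModel, LengthDist
from .sample import ConfigError, derive_seed

log = logging.getLogger("taxoskim")

STAGES = ["qc", "mine-loci", "consensus", "place", "map-genome", "classify",
          "depth-benchmark"]


@dataclass
class RunConfig:
    reads_fastq: str
    marker_panel_fasta: str
    outdir: str
    seed: int
    genome_fasta: str | None = None
    genes_gff3: str | None = None
    class_panel_fasta: str | None = None
    placement_panel_fasta: str | None = None
    stages: Sequence[str] = tuple(STAGES)
    qc: dict = field(default_factory=dict)
    mine_loci: dict = field(default_factory=dict)
    map_genome: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    depth_benchmark: dict = field(default_factory=dict)
    verbosity: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        for name in ("reads_fastq", "marker_panel_fasta", "genome_fasta",
                     "genes_gff3", "class_panel_fasta", "placement_panel_fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _error_model(block: dict) -> ErrorModel:
    d = dict(block.get("error_model", {}))
    ld = d.pop("length_dist", None)
    model = ErrorModel(**d) if d else ErrorModel()
    if ld:
        model.length_dist = LengthDist(**ld)
    return model


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the report dict (also written
    to ``<outdir>/report.json``). A stage failure aborts the run with the
    failing stage named; earlier outputs are retained."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")

    report: dict = {"seed": config.seed, "stages_run": list(config.stages)}
    reads = seqio.read_fastq(config.reads_fastq)
    panel = seqio.read_fasta(config.marker_panel_fasta)

    qc_reads = reads
    mining = None
    locus_consensus: dict[str, cons.ConsensusResult] = {}

    for stage in [s for s in STAGES if s in set(config.stages)]:
        log.info("stage=%s seed=%d params=%s", stage, config.seed,
                 getattr(config, stage.replace("-", "_"), {}))
        try:
            if stage == "qc":
                params = qcmod.QCParams(**config.qc)
                qc_reads, summary = qcmod.filter_reads(reads, params)
                seqio.write_fastq(qc_reads, outdir / "qc_reads.fastq")
                report["qc"] = {"params": dataclasses.asdict(params),
                                **summary.as_dict()}
            elif stage == "mine-loci":
                mining = mine_loci(qc_reads, panel, **config.mine_loci)
                mining.assignments.to_csv(outdir / "locus_assignments.tsv",
                                          sep="\t", index=False)
                report["mine_loci"] = {
                    "n_reads_in": len(qc_reads),
                    "n_assigned": int(len(mining.assignments)),
                    "mean_depth": {k: round(v, 4) for k, v in
                                   sorted(mining.mean_depth.items())},
                }
            elif stage == "consensus":
                if mining is None:
                    mining = mine_loci(qc_reads, panel, **config.mine_loci)
                block = {}
                recs = []
                for locus in panel:
                    mask = mining.assignments.locus_id == locus.id
                    rid = set(mining.assignments.read_id[mask])
                    sub = [r for r in qc_reads if r.id in rid]
                    if not sub:
                        continue
                    res = cons.consensus_from_reads(sub, locus)
                    locus_consensus[locus.id] = res
                    block[locus.id] = {
                        "n_reads": len(sub), "length": len(res.sequence),
                        "n_uncovered": res.n_uncovered,
                        "mean_depth": round(float(res.depths.mean()), 3),
                    }
                    from .sample import ReferenceSeq
                    recs.append(ReferenceSeq(id=f"{locus.id}_consensus",
                                             bases=res.sequence, role="consensus"))
                if recs:
                    seqio.write_fasta(recs, outdir / "locus_consensus.fasta")
                report["consensus"] = block
            elif stage == "place":
                if config.placement_panel_fasta is None:
                    report["place"] = {}
                    continue
                ppanel = seqio.read_fasta(config.placement_panel_fasta)
                block = {}
                tables = []
                for locus_id, res in sorted(locus_consensus.items()):
                    sub = [p for p in ppanel if p.id.startswith(locus_id)] or ppanel
                    rep = community.place_consensus(res.sequence, sub,
                                                    query_id=locus_id)
                    block[locus_id] = {
                        "top_hit": rep.top_hit, "top_taxon": rep.top_taxon,
                        "top_identity_pct": round(float(rep.ranking.identity_pct.iloc[0]), 3),
                    }
                    tables.append(rep.ranking.assign(query=locus_id))
                if tables:
                    pd.concat(tables).to_csv(outdir / "placement.tsv",
                                             sep="\t", index=False)
                report["place"] = block
            elif stage == "map-genome":
                if config.genome_fasta is None:
                    report["map_genome"] = {}
                    continue
                genome = seqio.read_fasta(config.genome_fasta)
                genes = (seqio.read_gff3(config.genes_gff3)
                         if config.genes_gff3 else None)
                res = map_genome(reads, genome, genes, **config.map_genome)
                alignments_to_outfmt6(res.alignments).to_csv(
                    outdir / "genome_hits.tsv", sep="\t", index=False)
                res.coverage.per_gene.to_csv(outdir / "gene_coverage.tsv",
                                             sep="\t", index=False)
                report["map_genome"] = {
                    "n_unique_hits": len(res.unique_hits),
                    **res.coverage.totals,
                    "per_chromosome": res.coverage.per_chromosome.to_dict("records"),
                }
            elif stage == "classify":
                if config.class_panel_fasta is None:
                    report["classify"] = {}
                    continue
                cpanel = seqio.read_fasta(config.class_panel_fasta)
                res = community.classify_reads(qc_reads, cpanel, **config.classify)
                res.summary.to_csv(outdir / "taxon_summary.tsv", sep="\t",
                                   index=False)
                res.assignments.to_csv(outdir / "read_assignments.tsv",
                                       sep="\t", index=False)
                report["classify"] = {
                    "n_reads": len(qc_reads),
                    "summary": res.summary.round(6).to_dict("records"),
                }
            elif stage == "depth-benchmark":
                block = dict(config.depth_benchmark)
                model = _error_model(block)
                locus_id = block.get("locus", panel[0].id)
                locus = next(p for p in panel if p.id == locus_id)
                donor = (seqio.read_fasta(config.genome_fasta)[0]
                         if config.genome_fasta else panel[-1])
                df, summary = cons.run_depth_benchmark(
                    locus, donor, model,
                    depths=block.get("depths", cons.DEFAULT_DEPTHS),
                    replicates=block.get("replicates", 3),
                    seed=derive_seed(config.seed, "depth-benchmark"),
                    flank_len=block.get("flank_len", 100),
                )
                df.to_csv(outdir / "depth_benchmark.tsv", sep="\t", index=False)
                report["depth_benchmark"] = {
                    "locus": locus_id,
                    "per_depth": {str(k): v for k, v in sorted(summary.items())},
                }
        except Exception as exc:   # noqa: BLE001 - report the failing stage
            _write_report(report, outdir)
            raise StageFailure(stage, exc) from exc

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")
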