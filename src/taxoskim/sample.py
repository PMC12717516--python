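"""Synthetic mixed-specimen generator.

Emulates the DNA content of a PCR-free genome-skimming library from a single
field specimen: a minority of bases from a target fungal genome (which
carries embedded rDNA/protein-coding barcode loci — ITS, LSU, SSU, TEF — and
annotated genes), the remainder from labeled contaminant organisms
(bacteria-like, a second fungus, arthropod traces). Every emitted read
carries a ground-truth label, so each downstream stage — QC, locus mining,
genome mapping, classification — can be scored exactly without any external
database or download.

References are i.i.d. uniform over {A,C,G,T}: maximum-entropy composition
keeps chance cross-taxon alignment identity near the 25% noise floor, which
is what makes the classification tests sharp. Contaminants are drawn
independently (inter-taxon identity ~ random); use :func:`mutate_relative`
to manufacture a controlled near relative of any reference.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqio

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent sample configurations."""


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed derivation: crc32 over the token string, < 2^31."""
    key = ":".join([str(seed), *map(str, tokens)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def random_bases(n: int, rng: np.random.Generator) -> str:
    return _BASE_ARR[rng.integers(0, 4, size=n)].tobytes().decode()


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval on a reference, 1-based inclusive."""
    id: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class ReferenceSeq:
    """A labeled reference sequence (genome, marker locus, or contaminant)."""
    id: str
    bases: str
    role: str = ""          # endogenous_genome | marker_locus | contaminant
    taxon_label: str = ""
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.bases:
            raise ConfigError(f"reference {self.id!r} has empty sequence")
        seen = set()
        for f in self.features:
            if not (1 <= f.start <= f.end <= len(self.bases)):
                raise ConfigError(f"feature {f.id} outside [1,{len(self.bases)}]")
            if f.id in seen:
                raise ConfigError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one simulated read: source interval (1-based
    inclusive), strand, and introduced error counts."""
    read_id: str
    source_id: str
    source_start: int
    source_end: int
    strand: str
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0


@dataclass
class ContaminantSpec:
    taxon_label: str
    n_seqs: int
    seq_length: int


# Default mixture: qualitatively a bacteria-dominated library with a minority
# of target-fungus bases, some second-fungus signal and trace arthropod DNA —
# the typical composition of a skimmed fruiting-body specimen.
DEFAULT_CONTAMINANTS = (
    ContaminantSpec("soil_bacterium_A", 2, 12_000),
    ContaminantSpec("soil_bacterium_B", 1, 12_000),
    ContaminantSpec("mycoparasitic_fungus", 1, 12_000),
    ContaminantSpec("fungus_gnat_arthropod", 1, 12_000),
)

DEFAULT_PROPORTIONS = {
    "target_fungus": 0.20,
    "soil_bacterium_A": 0.35,
    "soil_bacterium_B": 0.20,
    "mycoparasitic_fungus": 0.18,
    "fungus_gnat_arthropod": 0.07,
}

# Typical fungal barcode-locus lengths (bp): ITS region, LSU (LR0R–LR5
# fragment), SSU, TEF coding fragment.
DEFAULT_MARKER_LOCI = {"ITS": 600, "LSU": 900, "SSU": 1500, "TEF": 1000}


@dataclass
class SampleConfig:
    genome_length: int = 50_000
    marker_loci: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_MARKER_LOCI))
    gene_count: int = 25
    gene_length_range: tuple[int, int] = (500, 2000)
    contaminants: Sequence[ContaminantSpec] = DEFAULT_CONTAMINANTS
    proportions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    total_bases: int = 500_000
    target_taxon: str = "target_fungus"
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        for name, ln in self.marker_loci.items():
            if ln <= 0:
                raise ConfigError(f"marker locus {name} has non-positive length")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid gene_length_range")
        if any(p < 0 or p > 1 for p in self.proportions.values()):
            raise ConfigError("proportions must lie in [0,1]")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("proportions must sum to 1")
        taxa = {self.target_taxon} | {c.taxon_label for c in self.contaminants}
        unknown = set(self.proportions) - taxa
        if unknown:
            raise ConfigError(f"proportions reference unknown taxa: {sorted(unknown)}")
        if sum(self.marker_loci.values()) > self.genome_length:
            raise ConfigError("marker loci do not fit inside the genome")
        if hi > self.genome_length:
            raise ConfigError("gene length range exceeds genome length")


@dataclass
class SampleReferences:
    """make_references() output: the genome (gene features attached), the
    embedded marker-locus panel, the genome coordinates of each locus
    (1-based inclusive), and the contaminant panel."""
    genome: ReferenceSeq
    loci: list[ReferenceSeq]
    locus_intervals: dict[str, tuple[int, int]]
    contaminants: list[ReferenceSeq]

    def all_references(self) -> list[ReferenceSeq]:
        return [self.genome, *self.contaminants]

    def by_taxon(self) -> dict[str, list[ReferenceSeq]]:
        out: dict[str, list[ReferenceSeq]] = {}
        for r in self.all_references():
            out.setdefault(r.taxon_label, []).append(r)
        return out

    def gff_rows(self) -> list[tuple]:
        rows = [
            (self.genome.id, "taxoskim", "rRNA", s, e, "+", name)
            for name, (s, e) in sorted(self.locus_intervals.items())
        ]
        rows += [
            (self.genome.id, "taxoskim", "gene", f.start, f.end, f.strand, f.id)
            for f in self.genome.features
        ]
        return rows

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta([self.genome], outdir / "genome.fasta")
        seqio.write_fasta(self.loci, outdir / "markers.fasta")
        seqio.write_fasta(self.contaminants, outdir / "contaminants.fasta")
        seqio.write_gff3(self.gff_rows(), outdir / "genome.gff3")


def _place_disjoint(lengths: Sequence[int], genome_length: int,
                    rng: np.random.Generator, max_tries: int = 10_000) -> list[int]:
    """Sample disjoint 0-based start positions for the given lengths."""
    placed: list[tuple[int, int]] = []   # (start, end) half-open
    starts = []
    for ln in lengths:
        if ln > genome_length:
            raise ConfigError("interval longer than genome")
        for _ in range(max_tries):
            s = int(rng.integers(0, genome_length - ln + 1))
            if all(s + ln <= a or s >= b for a, b in placed):
                placed.append((s, s + ln))
                starts.append(s)
                break
        else:
            raise ConfigError("could not place disjoint intervals; genome too crowded")
    return starts


def make_references(config: SampleConfig) -> SampleReferences:
    """Generate the labeled reference set for one synthetic specimen.

    Deterministic in ``config.seed``: the genome, embedded marker loci,
    gene annotation and contaminant panel are pure functions of the config.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "references"))

    genome_bases = random_bases(config.genome_length, rng)

    locus_names = list(config.marker_loci)
    starts = _place_disjoint([config.marker_loci[n] for n in locus_names],
                             config.genome_length, rng)
    locus_intervals = {
        name: (s + 1, s + config.marker_loci[name])
        for name, s in zip(locus_names, starts)
    }

    lo, hi = config.gene_length_range
    genes = []
    for i in range(config.gene_count):
        ln = int(rng.integers(lo, hi + 1))
        s = int(rng.integers(0, config.genome_length - ln + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneFeature(id=f"gene{i + 1:04d}", start=s + 1, end=s + ln, strand=strand))

    genome = ReferenceSeq(
        id="target_genome", bases=genome_bases, role="endogenous_genome",
        taxon_label=config.target_taxon, features=genes,
    )
    loci = [
        ReferenceSeq(
            id=name,
            bases=genome_bases[locus_intervals[name][0] - 1: locus_intervals[name][1]],
            role="marker_locus", taxon_label=config.target_taxon,
        )
        for name in locus_names
    ]

    contaminants = []
    for spec in config.contaminants:
        for k in range(spec.n_seqs):
            crng = np.random.default_rng(derive_seed(config.seed, "contaminant", spec.taxon_label, k))
            contaminants.append(ReferenceSeq(
                id=f"{spec.taxon_label}_ctg{k + 1}",
                bases=random_bases(spec.seq_length, crng),
                role="contaminant", taxon_label=spec.taxon_label,
            ))
    return SampleReferences(genome, loci, locus_intervals, contaminants)


def mutate_relative(ref: ReferenceSeq, divergence: float, seed: int,
                    id_suffix: str = "_relative") -> tuple[ReferenceSeq, int]:
    """Derive a near relative by i.i.d. substitution at rate ``divergence``.

    Each position is substituted independently with probability
    ``divergence``, to a uniform alternative base; returns the relative and
    the realized substitution count.
    """
    if not (0 <= divergence < 1):
        raise ConfigError("divergence must lie in [0,1)")
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(ref.bases.encode(), dtype=np.uint8).copy()
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    idx = lut[codes]
    hit = rng.random(len(idx)) < divergence
    shift = rng.integers(1, 4, size=len(idx))
    new_idx = np.where(hit, (idx + shift) % 4, idx)
    n_sub = int(np.count_nonzero(new_idx != idx))
    rel = replace(
        ref,
        id=ref.id + id_suffix,
        bases=_BASE_ARR[new_idx].tobytes().decode(),
        taxon_label=(ref.taxon_label + "_relative") if ref.taxon_label else "relative",
        features=[],
    )
    return rel, n_sub


def make_relative_panel(loci: Sequence[ReferenceSeq], divergences: Sequence[float],
                        seed: int) -> list[ReferenceSeq]:
    """For each marker locus, emit relatives at the given divergences —
    a stand-in for a reference database of described sister species."""
    panel = []
    for locus in loci:
        for d in divergences:
            rel, _ = mutate_relative(
                locus, d, derive_seed(seed, "relative", locus.id, f"{d:.4f}"),
                id_suffix=f"_rel{int(round(d * 100))}",
            )
            panel.append(rel)
    return panel


def make_sample(config: SampleConfig, model, refs: SampleReferences | None = None):
    """Simulate the mixed read pool: per-taxon base budgets follow
    ``config.proportions`` of ``config.total_bases``; reads are generated by
    :func:`taxoskim.read_model.simulate_reads` per source sequence.

    Returns ``(reads, labels, refs)`` where labels is the TruthLabel table
    (one row per read, exactly).
    """
    from .read_model import simulate_reads

    config.validate()
    if refs is None:
        refs = make_references(config)

    by_taxon = refs.by_taxon()
    reads, labels = [], []
    for taxon in sorted(config.proportions):
        budget = config.proportions[taxon] * config.total_bases
        if budget <= 0:
            continue
        sources = by_taxon.get(taxon, [])
        if not sources:
            raise ConfigError(f"no reference for taxon {taxon!r}")
        total_len = sum(len(s) for s in sources)
        for src in sources:
            src_budget = budget * len(src) / total_len
            if src_budget <= 0:
                continue
            depth = src_budget / len(src)
            sseed = derive_seed(config.seed, "sample", taxon, src.id)
            r, t = simulate_reads(src, model, depth=depth, seed=sseed,
                                  id_prefix=f"{src.id}.s{config.seed}")
            reads.extend(r)
            labels.extend(t)
    return reads, labels, refs


def sample_composition(labels) -> pd.DataFrame:
    """Realized per-source read/base tallies from a TruthLabel table."""
    df = labels if isinstance(labels, pd.DataFrame) else seqio.truth_table(labels)
    if df.empty:
        return pd.DataFrame(columns=["source_id", "n_reads", "n_bases"])
    g = df.assign(n_bases=df.source_end - df.source_start + 1 - df.n_del + df.n_ins)
    out = g.groupby("source_id", as_index=False).agg(
        n_reads=("read_id", "size"), n_bases=("n_bases", "sum"))
    return out
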