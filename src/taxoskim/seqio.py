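"""Serialization helpers: FASTA / FASTQ (Phred+33) / GFF3 / truth-label TSV.

Sequence records travel through Biopython's SeqIO; the thin wrappers here
only adapt between the package's dataclasses and SeqRecord, and fix the
panel-FASTA description syntax ``>seqid taxon=<label> role=<role>``.
All genomic coordinates are 1-based inclusive on disk (GFF3 convention)
and 0-based half-open in memory.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TRUTH_COLUMNS = [
    "read_id", "source_id", "source_start", "source_end",
    "strand", "n_sub", "n_ins", "n_del",
]

_KV_RE = re.compile(r"(\w+)=(\S+)")


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write ReferenceSeq-like objects (``id``, ``bases``, optional
    ``taxon_label``/``role``) as FASTA with key=value descriptions."""
    seqrecs = []
    for r in records:
        desc_parts = []
        if getattr(r, "taxon_label", ""):
            desc_parts.append(f"taxon={r.taxon_label}")
        if getattr(r, "role", ""):
            desc_parts.append(f"role={r.role}")
        seqrecs.append(SeqRecord(Seq(r.bases), id=r.id, description=" ".join(desc_parts)))
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fasta(path: str | Path) -> list:
    """Read FASTA into ReferenceSeq objects, recovering taxon/role tags."""
    from .sample import ReferenceSeq

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(_KV_RE.findall(rec.description))
        out.append(ReferenceSeq(
            id=rec.id,
            bases=str(rec.seq).upper(),
            role=tags.get("role", ""),
            taxon_label=tags.get("taxon", ""),
        ))
    return out


def write_fastq(reads: Iterable, path: str | Path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_fastq(path: str | Path) -> list:
    from .read_model import Read

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(Read(
            id=rec.id,
            bases=str(rec.seq).upper(),
            quals=np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64),
        ))
    return out


def write_gff3(features: Sequence[tuple], path: str | Path) -> None:
    """Write (seqid, source, ftype, start, end, strand, feature_id) rows,
    start/end 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, strand, fid in features:
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\tID={fid}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Parse the 9-column GFF3 body into a DataFrame
    (seqid, source, type, start, end, strand, feature_id)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append({
                "seqid": f[0], "source": f[1], "type": f[2],
                "start": int(f[3]), "end": int(f[4]), "strand": f[6],
                "feature_id": attrs.get("ID", ""),
            })
    return pd.DataFrame(rows, columns=["seqid", "source", "type", "start", "end", "strand", "feature_id"])


def write_truth_table(labels: Iterable, path: str | Path) -> None:
    df = truth_table(labels)
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "source_id": str, "strand": str})


def truth_table(labels: Iterable) -> pd.DataFrame:
    rows = [{
        "read_id": t.read_id, "source_id": t.source_id,
        "source_start": t.source_start, "source_end": t.source_end,
        "strand": t.strand, "n_sub": t.n_sub, "n_ins": t.n_ins, "n_del": t.n_del,
    } for t in labels]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)
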