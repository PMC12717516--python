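"""Endogenous/exogenous read classification and identity-ranking placement.

``classify_reads`` plays the role of an exhaustive nucleotide-database
search in a field setting: each read is assigned to the taxon of its best
retained hit against a user-supplied labeled panel, giving a snapshot of the
specimen's associated and incidental organisms (its microbiome plus host
traces) next to the endogenous fraction. Reads with no retained hit are
reported in an explicit "unassigned" row, so read counts are conserved
exactly. Assignment is best-hit-only — the closest identifiable taxon —
with no lowest-common-ancestor logic.

``place_consensus`` ranks a mined locus consensus against a marker panel of
candidate relatives by global-alignment identity — the desk analog of
reading a barcode search result ("closest match at >97% ITS identity").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .align import (DEFAULT_SCHEME, Alignment, KmerIndex, ScoringScheme,
                    encode, global_identity, local_align)
from .read_model import Read
from .sample import ReferenceSeq

UNASSIGNED = "unassigned"


@dataclass
class ClassificationResult:
    summary: pd.DataFrame        # taxon_label, n_reads, n_bases, fraction_reads, fraction_bases
    assignments: pd.DataFrame    # read_id, taxon_label, subject_id, identity_pct, aln_len, evalue


def classify_reads(reads: Sequence[Read], panel: Sequence[ReferenceSeq],
                   evalue_max: float = 1e-3, min_aln_len: int = 200,
                   min_identity: float = 80.0,
                   scheme: ScoringScheme = DEFAULT_SCHEME,
                   **align_kwargs) -> ClassificationResult:
    """Assign each read to the taxon of its best retained panel hit.

    Retention filters: E-value <= ``evalue_max``, alignment length >=
    ``min_aln_len``, identity >= ``min_identity``. Ties break by higher
    identity, then panel sequence id. Summary rows (including the
    unassigned row) are sorted by base fraction, descending.
    """
    if not panel:
        raise ValueError("empty panel")
    ids = [p.id for p in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate panel ids")
    if any(not p.taxon_label for p in panel):
        raise ValueError("panel sequences must carry taxon labels")

    seed_len = align_kwargs.get("seed_len", 11)
    indexes = {p.id: KmerIndex(encode(p.bases), seed_len) for p in panel}
    db_len = sum(len(p) for p in panel)
    taxon_of = {p.id: p.taxon_label for p in panel}

    rows = []
    for read in reads:
        best: Alignment | None = None
        for p in sorted(panel, key=lambda p: p.id):
            for a in local_align(read.bases, p.bases, scheme=scheme,
                                 query_id=read.id, subject_id=p.id,
                                 db_len=db_len, subject_index=indexes[p.id],
                                 **align_kwargs):
                if (a.evalue > evalue_max or a.aligned_columns < min_aln_len
                        or a.identity_pct < min_identity):
                    continue
                if best is None or (-a.raw_score, -a.identity_pct, a.subject_id) < \
                        (-best.raw_score, -best.identity_pct, best.subject_id):
                    best = a
        if best is None:
            rows.append({"read_id": read.id, "taxon_label": UNASSIGNED,
                         "subject_id": "", "identity_pct": float("nan"),
                         "aln_len": 0, "evalue": float("nan"),
                         "n_bases": len(read)})
        else:
            rows.append({"read_id": read.id, "taxon_label": taxon_of[best.subject_id],
                         "subject_id": best.subject_id,
                         "identity_pct": best.identity_pct,
                         "aln_len": best.aligned_columns, "evalue": best.evalue,
                         "n_bases": len(read)})
    assignments = pd.DataFrame(rows, columns=[
        "read_id", "taxon_label", "subject_id", "identity_pct", "aln_len",
        "evalue", "n_bases"])

    taxa = sorted({p.taxon_label for p in panel} | {UNASSIGNED})
    total_reads = len(reads)
    total_bases = int(assignments.n_bases.sum()) if len(assignments) else 0
    srows = []
    for t in taxa:
        sub = assignments[assignments.taxon_label == t]
        n_r, n_b = len(sub), int(sub.n_bases.sum()) if len(sub) else 0
        srows.append({
            "taxon_label": t, "n_reads": n_r, "n_bases": n_b,
            "fraction_reads": n_r / total_reads if total_reads else 0.0,
            "fraction_bases": n_b / total_bases if total_bases else 0.0,
        })
    summary = (pd.DataFrame(srows)
               .sort_values(["fraction_bases", "taxon_label"],
                            ascending=[False, True])
               .reset_index(drop=True))
    return ClassificationResult(summary, assignments.drop(columns=["n_bases"]))


@dataclass
class PlacementReport:
    query_id: str
    ranking: pd.DataFrame    # panel_id, taxon_label, identity_pct, aln_len
    top_hit: str             # panel id of rank 1
    top_taxon: str


def place_consensus(consensus: str, panel: Sequence[ReferenceSeq],
                    query_id: str = "consensus") -> PlacementReport:
    """Rank panel members by global-alignment identity to the consensus.

    Ranking is strictly by identity percentage, ties broken by panel id;
    with a panel of candidate relatives the top hit identifies the closest
    described taxon, identity ~ 100*(1 - divergence).
    """
    if not consensus:
        raise ValueError("empty consensus sequence")
    if not panel:
        raise ValueError("empty panel")
    rows = []
    for p in panel:
        ident, n_match, n_mis, n_gap = global_identity(consensus, p.bases)
        rows.append({
            "panel_id": p.id, "taxon_label": p.taxon_label,
            "identity_pct": ident, "aln_len": n_match + n_mis + n_gap,
        })
    ranking = (pd.DataFrame(rows)
               .sort_values(["identity_pct", "panel_id"], ascending=[False, True])
               .reset_index(drop=True))
    top = ranking.iloc[0]
    return PlacementReport(query_id, ranking, str(top.panel_id), str(top.taxon_label))
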