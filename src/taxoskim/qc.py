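"""Read QC: mean-quality filtering, end cropping, and depth-by-quality curves.

Mean read quality follows the NanoFilt convention: per-base Phred scores are
converted to error probabilities, averaged, and converted back —
``-10*log10(mean(10^(-q/10)))`` — so a single bad stretch weighs as much as
it should. Filtering crops first (leading/trailing bases are the worst),
then re-evaluates quality and length on the cropped read.

Default thresholds are the ones used in field genome-skimming practice:
Q9 with 30 bp cropped from each end for locus mining, Q10 / 300 bp for
endogenous-genome mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .read_model import Read


@dataclass
class QCParams:
    min_q: float = 9.0
    crop_head: int = 30
    crop_tail: int = 30
    min_len: int = 0

    def __post_init__(self):
        if min(self.min_q, self.crop_head, self.crop_tail, self.min_len) < 0:
            raise ValueError("QC parameters must be non-negative")


@dataclass
class QCSummary:
    n_reads_in: int
    n_reads_out: int
    total_bases_in: int
    total_bases_out: int
    read_n50: int
    quality_quantiles: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_reads_out > self.n_reads_in or self.total_bases_out > self.total_bases_in:
            raise ValueError("QC output exceeds input")

    def as_dict(self) -> dict:
        return {
            "n_reads_in": self.n_reads_in, "n_reads_out": self.n_reads_out,
            "total_bases_in": self.total_bases_in, "total_bases_out": self.total_bases_out,
            "read_n50": self.read_n50, "quality_quantiles": self.quality_quantiles,
        }


def mean_read_quality(quals: Sequence[int] | np.ndarray) -> float:
    """Phred-scaled mean error probability of a read."""
    q = np.asarray(quals, dtype=float)
    if q.size == 0:
        raise ValueError("empty quality list")
    p = np.power(10.0, -q / 10.0)
    return float(-10.0 * np.log10(p.mean()))


def n50(lengths: Sequence[int]) -> int:
    if not len(lengths):
        return 0
    ls = np.sort(np.asarray(lengths))[::-1]
    half = ls.sum() / 2
    return int(ls[np.searchsorted(np.cumsum(ls), half)])


def crop_read(read: Read, head: int, tail: int) -> Read | None:
    """Drop ``head``/``tail`` bases; None if nothing would remain."""
    if len(read) <= head + tail:
        return None
    end = len(read) - tail if tail else len(read)
    return Read(read.id, read.bases[head:end], read.quals[head:end], truth=read.truth)


def filter_reads(reads: Sequence[Read], params: QCParams) -> tuple[list[Read], QCSummary]:
    """Crop, then retain reads with mean quality >= min_q (boundary
    inclusive) and cropped length >= min_len."""
    kept: list[Read] = []
    bases_in = 0
    for r in reads:
        bases_in += len(r)
        c = crop_read(r, params.crop_head, params.crop_tail)
        if c is None or len(c) < max(params.min_len, 1):
            continue
        if mean_read_quality(c.quals) >= params.min_q:
            kept.append(c)
    quals = [mean_read_quality(r.quals) for r in kept]
    qq = {}
    if quals:
        qs = np.percentile(quals, [0, 25, 50, 75, 100])
        qq = {k: round(float(v), 3) for k, v in zip(["min", "q25", "median", "q75", "max"], qs)}
    summary = QCSummary(
        n_reads_in=len(reads), n_reads_out=len(kept),
        total_bases_in=bases_in, total_bases_out=sum(len(r) for r in kept),
        read_n50=n50([len(r) for r in kept]), quality_quantiles=qq,
    )
    return kept, summary


def depth_by_quality(reads: Sequence[Read], locus_refs: Sequence,
                     q_thresholds: Sequence[float], **mine_kwargs) -> pd.DataFrame:
    """Per-locus mean depth after filtering at each quality threshold.

    Reproduces the depth-versus-quality trade-off of skimmed libraries:
    permissive thresholds keep hundreds-fold locus depth, strict ones keep
    only a few fold. Depth is monotone non-increasing in the threshold.
    Rows: one per threshold; columns: ``min_q`` plus one per locus id.
    """
    from .align import mine_loci

    if not len(q_thresholds):
        raise ValueError("empty threshold list")
    thr = list(q_thresholds)
    if thr != sorted(thr):
        raise ValueError("thresholds must be sorted ascending")
    read_q = {r.id: mean_read_quality(r.quals) for r in reads}
    rows = []
    for t in thr:
        subset = [r for r in reads if read_q[r.id] >= t]
        res = mine_loci(subset, locus_refs, **mine_kwargs) if subset else None
        row = {"min_q": t}
        for locus in locus_refs:
            row[locus.id] = res.mean_depth.get(locus.id, 0.0) if res is not None else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
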