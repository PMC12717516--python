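"""ONT-like long-read error model: simulation and characterization.

The simulator plays the role a learned nanopore read simulator plays in a
real genome-skimming workflow: given a reference and a target fold-coverage
it draws read lengths from a lognormal, picks start and strand uniformly,
and corrupts each base with i.i.d. substitution / insertion / deletion
events. The default model totals 10% per-base error (5% substitution,
2.5% insertion, 2.5% deletion), matching the ~90% per-base accuracy of
ONT v9-chemistry reads; the split between event classes is configurable.

Two devices support consensus benchmarking of short references:

* :func:`add_flanks` pads a reference with flanking sequence copied from a
  related donor so simulated long reads can extend beyond the target gene —
  the flanks foster coverage at the gene ends and are never scored.
* ``min_len_quantile`` imposes a read-length floor at the given quantile of
  the configured length distribution (0.95 reproduces the long-read floor
  used when benchmarking gene-sized references).

The error process is deliberately i.i.d. per base — no homopolymer or k-mer
context — which keeps every downstream expectation analytic and testable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .sample import ReferenceSeq, TruthLabel, ConfigError, _BASE_ARR

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class LengthDist:
    """Lognormal read-length distribution with hard bounds (bp)."""
    mu: float = math.log(1000.0)   # median ~1 kb
    sigma: float = 0.55
    min_len: int = 200
    max_len: int = 20_000

    def quantile(self, q: float) -> float:
        from scipy.stats import norm
        return float(np.exp(self.mu + self.sigma * norm.ppf(q)))

    def sample(self, rng: np.random.Generator, floor: float | None = None) -> int:
        lo = self.min_len if floor is None else max(self.min_len, floor)
        for _ in range(1000):
            ln = float(rng.lognormal(self.mu, self.sigma))
            if lo <= ln <= self.max_len:
                return int(round(ln))
        return int(round(min(max(lo, self.min_len), self.max_len)))


@dataclass
class ErrorModel:
    """Per-base i.i.d. error rates, read-length distribution and quality
    emission (mean Phred for correct vs erroneous bases, with integer
    jitter of half-width ``q_jitter``)."""
    p_sub: float = 0.05
    p_ins: float = 0.025
    p_del: float = 0.025
    length_dist: LengthDist = field(default_factory=LengthDist)
    q_correct: int = 13
    q_error: int = 5
    q_jitter: int = 2

    def __post_init__(self):
        if min(self.p_sub, self.p_ins, self.p_del) < 0 or \
                self.p_sub + self.p_ins + self.p_del >= 1:
            raise ConfigError("error rates must be non-negative with sum < 1")
        if self.length_dist.min_len > self.length_dist.max_len:
            raise ConfigError("min read length exceeds max")
        for q in (self.q_correct, self.q_error):
            if not (0 <= q <= 93):
                raise ConfigError("Phred values must lie in [0, 93]")

    @property
    def total_error(self) -> float:
        return self.p_sub + self.p_ins + self.p_del

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, src: str | Path) -> "ErrorModel":
        try:
            is_file = Path(str(src)).exists()
        except OSError:
            is_file = False
        text = Path(src).read_text() if is_file else str(src)
        d = json.loads(text)
        d["length_dist"] = LengthDist(**d["length_dist"])
        return cls(**d)


@dataclass
class Read:
    id: str
    bases: str
    quals: np.ndarray
    truth: TruthLabel | None = None

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.bases) != len(self.quals):
            raise ValueError("|bases| != |quals|")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AugmentedReference:
    """A reference padded with donor-derived flanks; ``target_interval`` is
    the original reference inside the padded sequence, 1-based inclusive."""
    id: str
    bases: str
    target_interval: tuple[int, int]

    def __len__(self) -> int:
        return len(self.bases)


def add_flanks(target: ReferenceSeq | str, donor: ReferenceSeq | str,
               flank_len: int = 100) -> AugmentedReference:
    """Pad ``target`` with ``flank_len`` bp copied from each end region of
    ``donor`` (left flank from the donor's start, right flank from its end).

    The flanks exist only to let simulated reads run past the target's
    limits; consumers must score bases inside ``target_interval`` only.
    """
    tb = target.bases if isinstance(target, ReferenceSeq) else target
    db = donor.bases if isinstance(donor, ReferenceSeq) else donor
    tid = target.id if isinstance(target, ReferenceSeq) else "target"
    if flank_len < 0:
        raise ConfigError("flank_len must be non-negative")
    if len(db) < 2 * flank_len:
        raise ConfigError("donor shorter than 2 x flank_len")
    left = db[:flank_len]
    right = db[len(db) - flank_len:] if flank_len else ""
    return AugmentedReference(
        id=f"{tid}_flanked",
        bases=left + tb + right,
        target_interval=(flank_len + 1, flank_len + len(tb)),
    )


def _corrupt(codes: np.ndarray, model: ErrorModel, rng: np.random.Generator):
    """Apply i.i.d. per-base events to an int8-coded sequence.

    Per source base: deleted w.p. p_del, else substituted w.p. p_sub
    (uniform alternative); independently, one uniform base is inserted
    after each emitted base w.p. p_ins. Returns (out_codes, err_mask,
    n_sub, n_ins, n_del); err_mask flags substituted and inserted bases.
    """
    n = len(codes)
    u = rng.random(n)
    del_mask = u < model.p_del
    sub_mask = (~del_mask) & (u < model.p_del + model.p_sub)
    sub_shift = rng.integers(1, 4, size=n)
    emitted = codes.copy()
    emitted[sub_mask] = (emitted[sub_mask] + sub_shift[sub_mask]) % 4

    keep = ~del_mask
    out = emitted[keep]
    err = sub_mask[keep]
    ins_after = rng.random(len(out)) < model.p_ins
    n_ins = int(ins_after.sum())
    if n_ins:
        offs = np.cumsum(ins_after)
        final = np.empty(len(out) + n_ins, dtype=out.dtype)
        ferr = np.zeros(len(final), dtype=bool)
        pos = np.arange(len(out)) + np.concatenate(([0], offs[:-1]))
        final[pos] = out
        ferr[pos] = err
        ins_pos = pos[ins_after] + 1
        final[ins_pos] = rng.integers(0, 4, size=n_ins)
        ferr[ins_pos] = True
        out, err = final, ferr
    return out, err, int(sub_mask.sum()), n_ins, int(del_mask.sum())


def simulate_reads(ref, model: ErrorModel, depth: float, seed: int,
                   min_len_quantile: float | None = None,
                   id_prefix: str | None = None) -> tuple[list[Read], list[TruthLabel]]:
    """Simulate reads until total emitted bases reach ``depth`` x reference
    length (base-counting coverage, not read counts).

    Lengths beyond the reference are clamped to it; a hard minimum read
    length longer than the reference raises with a pointer to
    :func:`add_flanks`.
    """
    if depth <= 0:
        raise ConfigError("depth must be positive")
    bases = ref.bases if hasattr(ref, "bases") else str(ref)
    ref_id = getattr(ref, "id", "ref")
    L = len(bases)
    floor = model.length_dist.quantile(min_len_quantile) if min_len_quantile else None
    if model.length_dist.min_len > L:
        raise ConfigError(
            f"reference ({L} bp) shorter than the minimum read length "
            f"({model.length_dist.min_len} bp); pad it with add_flanks()")
    prefix = id_prefix if id_prefix is not None else f"{ref_id}.s{seed}"

    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    ref_codes = lut[np.frombuffer(bases.encode(), dtype=np.uint8)]

    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    labels: list[TruthLabel] = []
    total = 0
    goal = depth * L
    k = 0
    while total < goal:
        ln = min(model.length_dist.sample(rng, floor), L)
        start = int(rng.integers(0, L - ln + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        src = ref_codes[start:start + ln]
        if strand == "-":
            src = (3 - src)[::-1]
        out, err, n_sub, n_ins, n_del = _corrupt(src, model, rng)
        jitter = rng.integers(-model.q_jitter, model.q_jitter + 1, size=len(out))
        quals = np.where(err, model.q_error, model.q_correct) + jitter
        np.clip(quals, 0, 93, out=quals)
        rid = f"{prefix}.{k:06d}"
        truth = TruthLabel(rid, ref_id, start + 1, start + ln, strand,
                           n_sub=n_sub, n_ins=n_ins, n_del=n_del)
        reads.append(Read(rid, _BASE_ARR[out].tobytes().decode(), quals, truth=truth))
        labels.append(truth)
        total += len(out)
        k += 1
    return reads, labels


def characterize_reads(reads: Sequence[Read], reference: str | ReferenceSeq,
                       truth_mode: bool = False) -> ErrorModel:
    """Fit an :class:`ErrorModel` by aligning reads back to their reference.

    Uses a mismatch-averse, gap-friendly scoring (match 2 / mismatch -4 /
    gap open 1 / extend 2) so the traceback keeps true indels as indels
    instead of collapsing a nearby insertion/deletion pair into mismatch
    columns — the homology-search scoring would bias the rate split.
    """
    from .align import (CHARACTERIZATION_SCHEME, KmerIndex, encode,
                        local_align)

    bases = reference.bases if hasattr(reference, "bases") else str(reference)
    if truth_mode:
        return characterize([], reads=reads, truth_mode=True)
    index = KmerIndex(encode(bases), 11)
    alns = []
    for r in reads:
        a = local_align(r.bases, bases, scheme=CHARACTERIZATION_SCHEME,
                        query_id=r.id, subject_index=index)
        if a:
            alns.append(a[0])
    return characterize(alns, reads=reads)


def truth_identity(label: TruthLabel) -> float:
    """Alignment identity (%) implied by a read's truth error counts:
    matches / alignment columns, gap columns included."""
    span = label.source_end - label.source_start + 1
    cols = span + label.n_ins
    matches = span - label.n_del - label.n_sub
    return 100.0 * matches / cols


def characterize(alignments: Sequence, reads: Sequence[Read] | None = None,
                 truth_mode: bool = False) -> ErrorModel:
    """Estimate an :class:`ErrorModel` from column-level alignments.

    * ``p_sub`` = mismatch columns / (match + mismatch columns)
    * ``p_ins`` = inserted query bases / aligned subject bases
    * ``p_del`` = deleted subject bases / aligned subject bases

    With ``truth_mode=True`` the rates come from the reads' TruthLabel
    counts instead of alignment traces (requires ``reads``). The length
    distribution is fitted by log-moment matching to the read lengths when
    ``reads`` is given, else to aligned query spans.
    """
    if truth_mode:
        if not reads:
            raise ConfigError("truth_mode requires reads with truth labels")
        spans = np.array([r.truth.source_end - r.truth.source_start + 1 for r in reads])
        subs = sum(r.truth.n_sub for r in reads)
        ins = sum(r.truth.n_ins for r in reads)
        dels = sum(r.truth.n_del for r in reads)
        subj = int(spans.sum())
        mm_denom = subj - dels
        lengths = np.array([len(r) for r in reads], dtype=float)
    else:
        if not alignments:
            raise ConfigError("characterize() requires at least one alignment")
        subs = ins = dels = matches = 0
        lens = []
        for a in alignments:
            ops = a.ops
            matches += ops.count("=")
            subs += ops.count("X")
            ins += ops.count("I")
            dels += ops.count("D")
            lens.append(a.q_end - a.q_start + 1)
        subj = matches + subs + dels
        mm_denom = matches + subs
        if reads:
            lens = [len(r) for r in reads]
        lengths = np.asarray(lens, dtype=float)

    if subj == 0 or mm_denom == 0:
        raise ConfigError("alignments carry no aligned columns")
    p_sub = subs / mm_denom
    p_ins = ins / subj
    p_del = dels / subj
    logs = np.log(lengths)
    ld = LengthDist(mu=float(logs.mean()),
                    sigma=float(logs.std(ddof=0)) if len(logs) > 1 else 0.1,
                    min_len=int(lengths.min()), max_len=int(max(lengths.max(), lengths.min() + 1)))
    return ErrorModel(p_sub=p_sub, p_ins=p_ins, p_del=p_del, length_dist=ld)
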