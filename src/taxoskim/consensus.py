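"""Pileup consensus calling and the depth-accuracy benchmark.

Simulated (or mapped) reads are piled onto a reference; only columns inside
the target interval are scored, so donor-derived flanks added to foster
read length never influence the result. The consensus is a plurality vote
per column with fixed deterministic tie rules:

* base ties break by symbol order A < C < G < T;
* a deletion loses every tie (a base is emitted);
* an insertion between two columns is emitted only when a single inserted
  sequence is supported by more than half of the reads spanning that
  junction;
* uncovered target positions emit nothing and are tallied separately.

The rules never consult the truth sequence — in the benchmark the
reference IS the truth, and a tie-to-reference rule would deflate the
error estimate circularly.

Polymorphisms against a truth sequence are counted on a global end-to-end
alignment (match +1, mismatch -1, gap -2): every mismatch or gap column is
one polymorphism, so a 3 bp deletion counts as 3. The benchmark error is
``100 * (polymorphisms + uncovered target positions) / truth length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Alignment, global_identity, local_align, KmerIndex, encode
from .read_model import (AugmentedReference, ErrorModel, Read, add_flanks,
                         revcomp, simulate_reads)
from .sample import ReferenceSeq, derive_seed

BASE_ORDER = "ACGT"

DEFAULT_DEPTHS = (2, 5, 10, 25, 50, 75)


@dataclass
class PileupColumn:
    """Vote tallies at one reference position (1-based)."""
    ref_pos: int
    counts: dict[str, int]                 # keys A,C,G,T,del
    insertions: dict[str, int] = field(default_factory=dict)  # seq inserted AFTER this column
    spanning_next: int = 0                 # reads spanning the junction to the next column

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class Pileup:
    columns: list[PileupColumn]
    target_interval: tuple[int, int]


@dataclass
class ConsensusResult:
    sequence: str
    depths: np.ndarray          # per target position
    n_uncovered: int


def build_pileup(alignments: Sequence[Alignment], reads: Mapping[str, Read] | Sequence[Read],
                 reference: AugmentedReference | ReferenceSeq | str,
                 target_interval: tuple[int, int] | None = None) -> Pileup:
    """Pile aligned read bases onto the reference's target interval.

    ``alignments`` should hold one alignment per read (unique hits); each
    aligned base or deletion contributes to exactly one column, insertions
    are registered at the junction after the column they follow.
    """
    if not isinstance(reads, Mapping):
        reads = {r.id: r for r in reads}
    if target_interval is None:
        target_interval = getattr(reference, "target_interval",
                                  (1, len(reference.bases if hasattr(reference, "bases")
                                          else reference)))
    t0, t1 = target_interval
    L = t1 - t0 + 1
    counts = np.zeros((L, 5), dtype=np.int64)       # A C G T del
    ins: dict[int, dict[str, int]] = {}
    span = np.zeros(max(L - 1, 0), dtype=np.int64)  # junction i -> i+1 (0-based col idx)
    idx = {b: i for i, b in enumerate(BASE_ORDER)}

    for a in alignments:
        read = reads[a.query_id]
        seq = read.bases if a.strand == "+" else revcomp(read.bases)
        oq0, _ = a.oriented_query_interval(len(read))
        qi = oq0 - 1          # 0-based cursor on oriented query
        sj = a.s_start - 1    # 0-based cursor on subject
        pending_ins: list[str] = []
        for op in a.ops:
            if op in "=X":
                if pending_ins and t0 - 1 <= sj - 1 < t1 - 1:
                    col = sj - 1 - (t0 - 1)
                    reg = ins.setdefault(col, {})
                    s = "".join(pending_ins)
                    reg[s] = reg.get(s, 0) + 1
                pending_ins = []
                if t0 - 1 <= sj <= t1 - 1:
                    b = seq[qi]
                    if b in idx:
                        counts[sj - (t0 - 1), idx[b]] += 1
                qi += 1
                sj += 1
            elif op == "D":
                if pending_ins and t0 - 1 <= sj - 1 < t1 - 1:
                    col = sj - 1 - (t0 - 1)
                    reg = ins.setdefault(col, {})
                    s = "".join(pending_ins)
                    reg[s] = reg.get(s, 0) + 1
                pending_ins = []
                if t0 - 1 <= sj <= t1 - 1:
                    counts[sj - (t0 - 1), 4] += 1
                sj += 1
            else:  # I
                pending_ins.append(seq[qi])
                qi += 1
        if a.ops and sj != a.s_end:
            raise ValueError(f"trace inconsistent with coordinates for {a.query_id}")
        # junction spanning: subject positions fully inside the aligned span
        lo = max(a.s_start - 1, t0 - 1)
        hi = min(a.s_end - 1, t1 - 1)
        if hi > lo:
            span[lo - (t0 - 1): hi - (t0 - 1)] += 1

    columns = []
    for i in range(L):
        col = PileupColumn(
            ref_pos=t0 + i,
            counts={"A": int(counts[i, 0]), "C": int(counts[i, 1]),
                    "G": int(counts[i, 2]), "T": int(counts[i, 3]),
                    "del": int(counts[i, 4])},
            insertions=ins.get(i, {}),
            spanning_next=int(span[i]) if i < L - 1 else 0,
        )
        columns.append(col)
    return Pileup(columns, (t0, t1))


def call_consensus(pileup: Pileup) -> ConsensusResult:
    """Plurality consensus over the pileup's target interval."""
    if not pileup.columns:
        raise ValueError("empty pileup")
    out: list[str] = []
    depths = np.zeros(len(pileup.columns), dtype=np.int64)
    n_uncovered = 0
    for i, col in enumerate(pileup.columns):
        depths[i] = col.depth
        if col.depth == 0:
            n_uncovered += 1
        else:
            best_base, best_n = "A", col.counts["A"]
            for b in "CGT":                     # strict > keeps A<C<G<T tie order
                if col.counts[b] > best_n:
                    best_base, best_n = b, col.counts[b]
            if col.counts["del"] <= best_n:     # deletion loses all ties
                out.append(best_base)
        if col.insertions and col.spanning_next > 0:
            items = sorted(col.insertions.items(), key=lambda kv: (-kv[1], kv[0]))
            seq, n = items[0]
            if n * 2 > col.spanning_next:
                out.append(seq)
    return ConsensusResult("".join(out), depths, n_uncovered)


def polymorphism_count(consensus: str, truth: str, n_uncovered: int = 0
                       ) -> tuple[int, float]:
    """Polymorphisms between a consensus and the truth sequence, and the
    benchmark error percentage.

    Polymorphisms = mismatch + gap columns of the global alignment;
    ``error_pct = 100 * (polymorphisms + n_uncovered) / len(truth)``.
    """
    if not truth:
        raise ValueError("empty truth sequence")
    if not consensus:
        n_poly = len(truth)
    else:
        _, _, n_mis, n_gap = global_identity(consensus, truth)
        n_poly = n_mis + n_gap
    error_pct = 100.0 * (n_poly + n_uncovered) / len(truth)
    return n_poly, error_pct


@dataclass
class DepthTrial:
    depth: float
    replicate: int
    seed: int
    n_reads: int
    n_polymorphisms: int
    n_uncovered: int
    error_pct: float


def consensus_from_reads(reads: Sequence[Read], reference, target_interval=None,
                         scheme=None, **align_kwargs) -> ConsensusResult:
    """Align reads to a reference (best hit per read) and call consensus."""
    from .align import DEFAULT_SCHEME

    ref_bases = reference.bases if hasattr(reference, "bases") else str(reference)
    index = KmerIndex(encode(ref_bases), align_kwargs.get("seed_len", 11))
    hits = []
    for r in reads:
        alns = local_align(r.bases, ref_bases, scheme=scheme or DEFAULT_SCHEME,
                           query_id=r.id, subject_id=getattr(reference, "id", "ref"),
                           subject_index=index, **align_kwargs)
        if alns:
            hits.append(alns[0])
    pile = build_pileup(hits, reads, reference, target_interval)
    return call_consensus(pile)


def run_depth_benchmark(reference: ReferenceSeq, donor: ReferenceSeq,
                        model: ErrorModel, depths: Sequence[float] = DEFAULT_DEPTHS,
                        replicates: int = 3, seed: int = 0, flank_len: int = 100,
                        min_len_quantile: float | None = 0.95,
                        **align_kwargs) -> tuple[pd.DataFrame, dict]:
    """Consensus-accuracy-versus-depth benchmark.

    For each (depth, replicate): simulate reads over the flank-augmented
    reference, align them back, call the plurality consensus over the
    target interval, and score polymorphisms against the original
    reference. Deterministic per (seed, depth, replicate). Returns the
    trial table and a per-depth summary (mean/max error).
    """
    aug = add_flanks(reference, donor, flank_len)
    trials: list[DepthTrial] = []
    for depth in depths:
        for rep in range(1, replicates + 1):
            tseed = derive_seed(seed, "bench", depth, rep)
            reads, _ = simulate_reads(aug, model, depth=depth, seed=tseed,
                                      min_len_quantile=min_len_quantile)
            cons = consensus_from_reads(reads, aug, **align_kwargs)
            n_poly, err = polymorphism_count(cons.sequence, reference.bases,
                                             cons.n_uncovered)
            trials.append(DepthTrial(depth, rep, tseed, len(reads), n_poly,
                                     cons.n_uncovered, err))
    df = pd.DataFrame([t.__dict__ for t in trials])
    summary = {
        float(d): {
            "mean_error_pct": float(g.error_pct.mean()),
            "max_error_pct": float(g.error_pct.max()),
        }
        for d, g in df.groupby("depth")
    }
    return df, summary


def plot_depth_curve(df: pd.DataFrame, path=None):
    """Error percentage versus sequencing depth (log-x), one point per
    trial plus the per-depth mean."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(df.depth, df.error_pct, s=18, alpha=0.6, label="replicates")
    means = df.groupby("depth").error_pct.mean()
    ax.plot(means.index, means.values, "o-", color="firebrick", label="mean")
    ax.axhline(1.0, ls="--", color="grey", lw=1, label="1% error")
    ax.set_xscale("log")
    ax.set_xlabel("sequencing depth (fold)")
    ax.set_ylabel("consensus error (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
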