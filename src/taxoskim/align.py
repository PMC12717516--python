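"""Seed-and-extend local alignment with Karlin-Altschul statistics, plus the
two skimming searches built on it: barcode-locus mining and endogenous-genome
mapping with unique-hit coverage.

The engine seeds on exact k-mer matches (default k=11), clusters seed
diagonals, and runs a banded affine-gap Smith-Waterman extension around each
cluster; short pairs bypass seeding and get exhaustive Smith-Waterman, so on
small inputs the reported optimum equals the full dynamic program. E-values
use the ungapped Karlin-Altschul formula ``E = K*m*n*exp(-lambda*S)`` with
lambda solved from the substitution scores and background base frequencies;
with gapped raw scores this is the standard approximation — the contract is
the behaviour of the E-value cutoff, not absolute E-value exactness.

Filter defaults mirror genome-skimming practice: locus mining drops reads
under 200 bp and hits at identity <=80% (strict >80); genome mapping
pre-filters at Q10/300 bp, applies E <= 0.001, alignment length >= 300 and
identity >= 80, caps subjects and HSPs per pair at 10, and computes
chromosome- and gene-level coverage from unique hits (the single
best-scoring retained alignment per read).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._kernels import banded_gotoh_local, nw_global_linear
from .read_model import Read, revcomp
from .sample import GeneFeature, ReferenceSeq

_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def compute_lambda(match: int, mismatch: int,
                   base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda*s_ij) = 1 for a
    match/mismatch substitution matrix; requires a negative expected score."""
    p = np.asarray(base_freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("base frequencies must be a probability vector")
    p_match = float((p * p).sum())
    p_mis = 1.0 - p_match
    expected = p_match * match + p_mis * mismatch
    if expected >= 0:
        raise ValueError("expected score must be negative for lambda to exist")
    if match <= 0:
        raise ValueError("match score must be positive")

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + p_mis * math.exp(lam * mismatch) - 1.0

    hi = 1.0 / match
    while f(hi) <= 0:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12))


@dataclass(frozen=True)
class ScoringScheme:
    """Integer alignment scores plus ungapped Karlin-Altschul parameters.

    Defaults are the classic blastn-style +2/-3 with gap open 5 / extend 2
    (a gap of length L costs 5 + 2L); K defaults to 0.1 — absolute E-values
    are approximate, the 0.001 cutoff behaviour is the contract.
    """
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    K: float = 0.1
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @cached_property
    def lambda_(self) -> float:
        return compute_lambda(self.match, self.mismatch, self.base_freqs)

    def bit_score(self, raw_score: float) -> float:
        return (self.lambda_ * raw_score - math.log(self.K)) / math.log(2.0)

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lambda_ * raw_score)


DEFAULT_SCHEME = ScoringScheme()

# Error-profiling scoring: mismatches cost more than an isolated indel, so
# a true insertion/deletion pair separated by a few bases stays two gaps in
# the traceback instead of collapsing into mismatch columns.
CHARACTERIZATION_SCHEME = ScoringScheme(match=2, mismatch=-4, gap_open=1, gap_extend=2)


def evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin-Altschul expected number of chance hits scoring >= raw_score
    in an m x n search space."""
    return scheme.evalue(raw_score, m, n)


@dataclass
class Alignment:
    """A local alignment record, BLAST-flavoured.

    Coordinates are 1-based inclusive. Reverse-strand hits keep subject
    coordinates on the forward strand with strand '-'; query coordinates
    are always on the forward query (q_start <= q_end). ``ops`` is the
    column trace in oriented-query order: '=' match, 'X' mismatch,
    'I' query-only (insertion), 'D' subject-only (deletion).
    """
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    raw_score: int
    ops: str
    bit_score: float = 0.0
    evalue: float = math.inf

    @property
    def aligned_columns(self) -> int:
        return len(self.ops)

    @property
    def identities(self) -> int:
        return self.ops.count("=")

    @property
    def mismatches(self) -> int:
        return self.ops.count("X")

    @property
    def gaps(self) -> int:
        return len(self.ops) - self.identities - self.mismatches

    @property
    def gap_opens(self) -> int:
        n = 0
        prev = ""
        for c in self.ops:
            if c in "ID" and c != prev:
                n += 1
            prev = c
        return n

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aligned_columns

    @property
    def subject_span(self) -> int:
        return self.s_end - self.s_start + 1

    def oriented_query_interval(self, query_len: int) -> tuple[int, int]:
        """(start, end) of the aligned segment on the oriented query
        (reverse-complemented when strand is '-'), 1-based inclusive."""
        if self.strand == "+":
            return self.q_start, self.q_end
        return query_len - self.q_end + 1, query_len - self.q_start + 1


def _traceback(q, s, bi, bk, dlo, ptrH, ptrE, ptrF) -> tuple[list[str], int, int]:
    """Walk pointer matrices from the best cell; returns (ops reversed back
    to forward order, start_i, start_j), 0-based half-open anchors."""
    ops: list[str] = []
    i, k = bi, bk
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = ptrH[i, k]
            if p == 0:
                break
            if p == 1:
                j = i + dlo + k
                qa, sb = q[i - 1], s[j - 1]
                ops.append("=" if (qa == sb and qa < 4) else "X")
                i -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops.append("D")
            pe = ptrE[i, k]
            k -= 1
            if pe == 0:
                state = 0
        else:
            ops.append("I")
            pf = ptrF[i, k]
            i -= 1
            k += 1
            if pf == 0:
                state = 0
    ops.reverse()
    return ops, i, i + dlo + k


class KmerIndex:
    """Exact k-mer position index over an encoded subject sequence."""

    def __init__(self, codes: np.ndarray, k: int = 11):
        self.codes = codes
        self.k = k
        self.table: dict[int, np.ndarray] = {}
        n = len(codes)
        if n < k:
            return
        kmers, valid = _kmer_ints(codes, k)
        order = np.argsort(kmers, kind="stable")
        kmers_sorted = kmers[order]
        bounds = np.flatnonzero(np.diff(kmers_sorted)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(kmers_sorted)]))
        for a, b in zip(starts, ends):
            key = int(kmers_sorted[a])
            pos = order[a:b]
            pos = pos[valid[pos]]
            if len(pos):
                self.table[key] = np.sort(pos)

    def lookup(self, qcodes: np.ndarray) -> list[tuple[int, int]]:
        """(query_pos, subject_pos) pairs of shared k-mers, 0-based."""
        k = self.k
        if len(qcodes) < k or not self.table:
            return []
        kmers, valid = _kmer_ints(qcodes, k)
        hits = []
        for qp in np.flatnonzero(valid):
            pos = self.table.get(int(kmers[qp]))
            if pos is not None:
                for sp in pos:
                    hits.append((int(qp), int(sp)))
        return hits


def _kmer_ints(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(codes) - k + 1
    vals = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    c = codes.astype(np.int64)
    for t in range(k):
        window = c[t:t + n]
        vals = vals * 4 + np.where(window > 3, 0, window)
        ok &= window <= 3
    return vals, ok


def _cluster_diagonals(hits: list[tuple[int, int]], band_width: int) -> list[tuple[int, int, int]]:
    """Group seed diagonals; returns (dmin, dmax, n_seeds) per cluster."""
    diags = sorted(sp - qp for qp, sp in hits)
    clusters = []
    start = prev = diags[0]
    count = 1
    for d in diags[1:]:
        if d - prev <= band_width:
            prev = d
            count += 1
        else:
            clusters.append((start, prev, count))
            start = prev = d
            count = 1
    clusters.append((start, prev, count))
    clusters.sort(key=lambda c: (-c[2], c[0]))
    return clusters


def _align_one_strand(qcodes, scodes, index: KmerIndex | None, scheme: ScoringScheme,
                      seed_len: int, band_width: int, max_clusters: int,
                      small_len: int) -> list[tuple[int, list[str], int, int]]:
    """Returns candidate (score, ops, q0, s0) tuples, 0-based starts."""
    m, n = len(qcodes), len(scodes)
    out = []
    if min(m, n) <= small_len:
        best, bi, bk, ptrH, ptrE, ptrF = banded_gotoh_local(
            qcodes, scodes, -m, n, scheme.match, scheme.mismatch,
            scheme.gap_open, scheme.gap_extend)
        if best > 0:
            ops, i0, j0 = _traceback(qcodes, scodes, bi, bk, -m, ptrH, ptrE, ptrF)
            out.append((int(best), ops, i0, j0))
        return out
    if index is None:
        index = KmerIndex(scodes, seed_len)
    hits = index.lookup(qcodes)
    if not hits:
        return out
    pad = max(band_width // 2, 8)
    for dmin, dmax, _count in _cluster_diagonals(hits, band_width)[:max_clusters]:
        dlo = max(dmin - pad, -m)
        dhi = min(dmax + pad, n)
        best, bi, bk, ptrH, ptrE, ptrF = banded_gotoh_local(
            qcodes, scodes, dlo, dhi, scheme.match, scheme.mismatch,
            scheme.gap_open, scheme.gap_extend)
        if best > 0:
            ops, i0, j0 = _traceback(qcodes, scodes, bi, bk, dlo, ptrH, ptrE, ptrF)
            out.append((int(best), ops, i0, j0))
    return out


def local_align(query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                both_strands: bool = True, min_score: int = 1,
                seed_len: int = 11, band_width: int = 50, max_clusters: int = 8,
                small_len: int = 64, query_id: str = "query",
                subject_id: str = "subject", db_len: int | None = None,
                subject_index: KmerIndex | None = None) -> list[Alignment]:
    """Local alignments of query against subject (both strands by default),
    sorted by raw score descending; E-values computed against ``db_len``
    (defaults to the subject length)."""
    if not query or not subject:
        raise ValueError("empty sequence")
    qcodes = encode(query)
    scodes = encode(subject)
    m, n = len(qcodes), len(scodes)
    db = n if db_len is None else db_len
    results: list[Alignment] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        if strand == "+":
            qc = qcodes
        else:
            rc = qcodes[::-1]
            qc = np.where(rc < 4, 3 - rc, 4).astype(np.int8)
        cands = _align_one_strand(qc, scodes, subject_index, scheme, seed_len,
                                  band_width, max_clusters, small_len)
        for score, ops, q0, s0 in cands:
            if score < min_score:
                continue
            qlen_aln = sum(1 for c in ops if c in "=XI")
            slen_aln = sum(1 for c in ops if c in "=XD")
            oq_start, oq_end = q0 + 1, q0 + qlen_aln   # oriented query coords
            if strand == "+":
                f_start, f_end = oq_start, oq_end
            else:
                f_start, f_end = m - oq_end + 1, m - oq_start + 1
            aln = Alignment(
                query_id=query_id, subject_id=subject_id,
                q_start=f_start, q_end=f_end,
                s_start=s0 + 1, s_end=s0 + slen_aln,
                strand=strand, raw_score=score, ops="".join(ops),
                bit_score=scheme.bit_score(score),
                evalue=scheme.evalue(score, m, db),
            )
            results.append(aln)
    # dedupe identical spans (a seed cluster can rediscover the same HSP)
    seen = set()
    unique = []
    for a in sorted(results, key=lambda a: (-a.raw_score, -a.identity_pct, a.s_start, a.strand)):
        key = (a.strand, a.q_start, a.q_end, a.s_start, a.s_end)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    return unique


def global_identity(a: str, b: str, match: int = 1, mismatch: int = -1,
                    gap: int = -2) -> tuple[float, int, int, int]:
    """End-to-end alignment identity of two sequences.

    Returns (identity_pct, n_match, n_mismatch, n_gap_columns)."""
    if not a or not b:
        raise ValueError("empty sequence")
    qa, sb = encode(a), encode(b)
    _score, ptr = nw_global_linear(qa, sb, match, mismatch, gap)
    i, j = len(qa), len(sb)
    n_match = n_mis = n_gap = 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 1:
            if qa[i - 1] == sb[j - 1] and qa[i - 1] < 4:
                n_match += 1
            else:
                n_mis += 1
            i -= 1
            j -= 1
        elif p == 2:
            n_gap += 1
            j -= 1
        else:
            n_gap += 1
            i -= 1
    cols = n_match + n_mis + n_gap
    return 100.0 * n_match / cols, n_match, n_mis, n_gap


# ---------------------------------------------------------------------------
# locus mining
# ---------------------------------------------------------------------------

@dataclass
class MiningResult:
    assignments: pd.DataFrame        # read_id, locus_id, identity_pct, aln_len, score, s_start, s_end
    mean_depth: dict[str, float]     # aligned subject bases / locus length
    best_alignments: dict[str, Alignment]  # read_id -> assigned alignment


def mine_loci(reads: Sequence[Read], marker_panel: Sequence[ReferenceSeq],
              min_read_len: int = 200, min_identity: float = 80.0,
              max_targets: int = 10, evalue_max: float = 1e-3,
              min_aln_len: int = 100, scheme: ScoringScheme = DEFAULT_SCHEME,
              **align_kwargs) -> MiningResult:
    """Extract reads matching barcode loci.

    Reads shorter than ``min_read_len`` are excluded before alignment; a
    read is assigned to the locus of its best-scoring alignment whose
    identity is strictly greater than ``min_identity``, subject to the
    significance gate ``evalue <= evalue_max`` and ``aligned_columns >=
    min_aln_len`` (without it, a chance shared word at 100% identity would
    satisfy an identity-only filter). Mean depth per locus is total
    aligned subject bases over locus length.
    """
    if not marker_panel:
        raise ValueError("empty marker panel")
    panel = list(marker_panel)
    db_len = sum(len(p) for p in panel)
    indexes = {p.id: KmerIndex(encode(p.bases), align_kwargs.get("seed_len", 11))
               for p in panel}
    rows = []
    best_alns: dict[str, Alignment] = {}
    depth_bases = {p.id: 0 for p in panel}
    for read in reads:
        if len(read) < min_read_len:
            continue
        candidates: list[Alignment] = []
        for p in panel:
            alns = local_align(read.bases, p.bases, scheme=scheme,
                               query_id=read.id, subject_id=p.id, db_len=db_len,
                               subject_index=indexes[p.id], **align_kwargs)
            candidates.extend(a for a in alns
                              if a.identity_pct > min_identity
                              and a.evalue <= evalue_max
                              and a.aligned_columns >= min_aln_len)
        if not candidates:
            continue
        candidates.sort(key=lambda a: (-a.raw_score, -a.identity_pct, a.subject_id, a.s_start))
        best = candidates[0]
        best_alns[read.id] = best
        depth_bases[best.subject_id] += best.subject_span
        rows.append({
            "read_id": read.id, "locus_id": best.subject_id,
            "identity_pct": best.identity_pct, "aln_len": best.aligned_columns,
            "score": best.raw_score, "s_start": best.s_start, "s_end": best.s_end,
        })
    assignments = pd.DataFrame(
        rows, columns=["read_id", "locus_id", "identity_pct", "aln_len",
                       "score", "s_start", "s_end"])
    mean_depth = {p.id: depth_bases[p.id] / len(p) for p in panel}
    return MiningResult(assignments, mean_depth, best_alns)


# ---------------------------------------------------------------------------
# genome mapping and unique-hit coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageSummary:
    per_chromosome: pd.DataFrame   # chrom, length, covered_bases, mean_depth
    per_gene: pd.DataFrame         # gene_id, chrom, start, end, covered, covered_bases, mean_depth
    totals: dict

    def __post_init__(self):
        for _, row in self.per_chromosome.iterrows():
            if row.covered_bases > row.length:
                raise ValueError("covered bases exceed chromosome length")


@dataclass
class MappingResult:
    alignments: list[Alignment]          # all retained hits (capped)
    unique_hits: dict[str, Alignment]    # read_id -> best retained alignment
    coverage: CoverageSummary
    qc_summary: object = None


def _gene_table(genes, default_chrom: str) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        df = genes[genes["type"] == "gene"] if "type" in genes.columns else genes
        return df[["feature_id", "seqid", "start", "end"]].rename(
            columns={"feature_id": "gene_id", "seqid": "chrom"}).reset_index(drop=True)
    rows = [{"gene_id": g.id, "chrom": default_chrom, "start": g.start, "end": g.end}
            for g in genes]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def map_genome(reads: Sequence[Read], genome: ReferenceSeq | Sequence[ReferenceSeq],
               genes=None, min_q: float = 10.0, min_read_len: int = 300,
               evalue_max: float = 1e-3, min_aln_len: int = 300,
               min_identity: float = 80.0, max_targets: int = 10,
               max_hsps: int = 10, scheme: ScoringScheme = DEFAULT_SCHEME,
               **align_kwargs) -> MappingResult:
    """Map reads to the endogenous genome and summarize unique-hit coverage.

    Pipeline: pre-filter reads (mean quality >= min_q, length >=
    min_read_len), align, retain hits with E <= evalue_max then alignment
    length >= min_aln_len and identity >= min_identity, cap subjects per
    read and HSPs per subject pair, pick each read's unique hit (best
    score; ties by higher identity, then subject id, then s_start), and
    accumulate per-chromosome and per-gene coverage from unique hits only.
    A gene counts as hit when a unique hit overlaps it by >= 1 bp.
    """
    from .qc import mean_read_quality

    chroms = [genome] if isinstance(genome, ReferenceSeq) else list(genome)
    chrom_by_id = {c.id: c for c in chroms}
    if genes is None:
        gene_df = pd.DataFrame(
            [{"gene_id": gf.id, "chrom": c.id, "start": gf.start, "end": gf.end}
             for c in chroms for gf in getattr(c, "features", [])],
            columns=["gene_id", "chrom", "start", "end"])
    else:
        gene_df = _gene_table(genes, chroms[0].id)
    unknown = set(gene_df.chrom) - set(chrom_by_id)
    if unknown:
        raise ValueError(f"annotation references unknown chromosomes: {sorted(unknown)}")

    db_len = sum(len(c) for c in chroms)
    seed_len = align_kwargs.get("seed_len", 11)
    indexes = {c.id: KmerIndex(encode(c.bases), seed_len) for c in chroms}

    passed = [r for r in reads
              if len(r) >= min_read_len and mean_read_quality(r.quals) >= min_q]

    retained: list[Alignment] = []
    unique_hits: dict[str, Alignment] = {}
    for read in passed:
        per_subject: dict[str, list[Alignment]] = {}
        for c in chroms:
            alns = local_align(read.bases, c.bases, scheme=scheme,
                               query_id=read.id, subject_id=c.id,
                               db_len=db_len, subject_index=indexes[c.id],
                               **align_kwargs)
            good = [a for a in alns
                    if a.evalue <= evalue_max
                    and a.aligned_columns >= min_aln_len
                    and a.identity_pct >= min_identity]
            if good:
                per_subject[c.id] = good[:max_hsps]
        if not per_subject:
            continue
        subjects = sorted(per_subject,
                          key=lambda sid: (-per_subject[sid][0].raw_score, sid))[:max_targets]
        read_alns = [a for sid in subjects for a in per_subject[sid]]
        retained.extend(read_alns)
        unique_hits[read.id] = min(
            read_alns, key=lambda a: (-a.raw_score, -a.identity_pct, a.subject_id, a.s_start))

    coverage = coverage_from_unique_hits(unique_hits.values(), chroms, gene_df)
    return MappingResult(retained, unique_hits, coverage)


def coverage_from_unique_hits(hits: Iterable[Alignment], chroms: Sequence[ReferenceSeq],
                              gene_df: pd.DataFrame) -> CoverageSummary:
    depth = {c.id: np.zeros(len(c), dtype=np.int64) for c in chroms}
    endo_bases = 0
    for a in hits:
        depth[a.subject_id][a.s_start - 1:a.s_end] += 1
        endo_bases += a.subject_span
    chrom_rows = []
    for c in chroms:
        d = depth[c.id]
        chrom_rows.append({
            "chrom": c.id, "length": len(c),
            "covered_bases": int((d > 0).sum()),
            "mean_depth": float(d.sum() / len(c)),
        })
    gene_rows = []
    for _, g in gene_df.iterrows():
        d = depth[g.chrom][g.start - 1:g.end]
        gene_rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "start": int(g.start),
            "end": int(g.end), "covered": bool((d > 0).any()),
            "covered_bases": int((d > 0).sum()),
            "mean_depth": float(d.sum() / len(d)) if len(d) else 0.0,
        })
    per_gene = pd.DataFrame(gene_rows, columns=[
        "gene_id", "chrom", "start", "end", "covered", "covered_bases", "mean_depth"])
    per_chrom = pd.DataFrame(chrom_rows, columns=[
        "chrom", "length", "covered_bases", "mean_depth"])
    totals = {
        "endogenous_bases": int(endo_bases),
        "genes_hit": int(per_gene.covered.sum()) if len(per_gene) else 0,
        "n_genes": int(len(per_gene)),
        "covered_bases": int(per_chrom.covered_bases.sum()) if len(per_chrom) else 0,
    }
    return CoverageSummary(per_chrom, per_gene, totals)


OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                   "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def alignments_to_outfmt6(alignments: Iterable[Alignment]) -> pd.DataFrame:
    """BLAST outfmt-6 table; minus-strand hits follow the BLAST convention
    of swapped subject coordinates."""
    rows = []
    for a in alignments:
        s1, s2 = (a.s_start, a.s_end) if a.strand == "+" else (a.s_end, a.s_start)
        rows.append({
            "qseqid": a.query_id, "sseqid": a.subject_id,
            "pident": round(a.identity_pct, 3), "length": a.aligned_columns,
            "mismatch": a.mismatches, "gapopen": a.gap_opens,
            "qstart": a.q_start, "qend": a.q_end, "sstart": s1, "send": s2,
            "evalue": a.evalue, "bitscore": round(a.bit_score, 1),
        })
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
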