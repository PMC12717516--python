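"""Alignment engine: Karlin-Altschul statistics, Smith-Waterman oracle
equivalence, strand symmetry, locus-mining filters and unique-hit
genome coverage."""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio import Align

from taxoskim.align import (Alignment, ScoringScheme, alignments_to_outfmt6,
                            compute_lambda, local_align, map_genome, mine_loci)
from taxoskim.qc import QCParams, filter_reads
from taxoskim.read_model import ErrorModel, Read, revcomp, simulate_reads
from taxoskim.sample import (GeneFeature, ReferenceSeq, SampleConfig,
                             make_sample, random_bases)


def _bio_local_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scheme.match
    a.mismatch_score = scheme.mismatch
    # Biopython charges open for the first gapped position; ours charges
    # open + extend for a length-1 gap.
    a.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    a.extend_gap_score = -scheme.gap_extend
    return a


class TestLambda:
    def test_plus_one_minus_one_closed_form(self):
        """(1/4)e^l + (3/4)e^-l = 1 solves to e^l = 3."""
        assert compute_lambda(1, -1) == pytest.approx(math.log(3), abs=1e-9)

    def test_numeric_root_oracle(self):
        """Brute-force scan for the sign change of the generating function
        (above the trivial root at zero)."""
        lam = compute_lambda(1, -2)
        grid = np.linspace(0.5, 3, 250001)
        f = 0.25 * np.exp(grid) + 0.75 * np.exp(-2 * grid) - 1
        crossing = np.flatnonzero(np.diff(np.sign(f)) > 0)
        assert len(crossing) == 1
        assert lam == pytest.approx(grid[crossing[0]], abs=1e-4)

    def test_score_scaling_scales_lambda_inversely(self):
        assert compute_lambda(2, -2) == pytest.approx(compute_lambda(1, -1) / 2)
        assert compute_lambda(3, -3) == pytest.approx(compute_lambda(1, -1) / 3)

    def test_non_negative_expected_score_rejected(self):
        with pytest.raises(ValueError):
            compute_lambda(3, -1)  # E[s] = 0.25*3 - 0.75*1 = 0


class TestEvalue:
    SCHEME = ScoringScheme(match=1, mismatch=-1, K=0.1)

    def test_linear_in_search_space(self):
        e1 = self.SCHEME.evalue(30, 1000, 1000)
        assert self.SCHEME.evalue(30, 1000, 2000) == pytest.approx(2 * e1)

    def test_decreasing_in_score_to_zero(self):
        es = [self.SCHEME.evalue(s, 1000, 1000) for s in (10, 30, 60, 600)]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert es[-1] < 1e-100

    def test_direct_formula_value(self):
        expected = 0.1 * 1000 * 1000 * math.exp(-math.log(3) * 60)
        assert self.SCHEME.evalue(60, 1000, 1000) == pytest.approx(expected, rel=1e-9)


class TestLocalAlign:
    def test_identical_300mer(self):
        s = random_bases(300, np.random.default_rng(1))
        hits = local_align(s, s)
        assert hits[0].raw_score == 600
        assert hits[0].identity_pct == 100.0
        assert hits[0].aligned_columns == 300
        assert (hits[0].q_start, hits[0].q_end) == (1, 300)

    def test_smith_waterman_oracle_equivalence(self):
        """Optimal raw scores equal exhaustive affine-gap Smith-Waterman
        (Biopython) on 200 random pairs of length <= 60."""
        scheme = ScoringScheme()
        oracle = _bio_local_aligner(scheme)
        rng = np.random.default_rng(42)
        for _ in range(200):
            q = random_bases(int(rng.integers(5, 61)), rng)
            s = random_bases(int(rng.integers(5, 61)), rng)
            mine = local_align(q, s, scheme=scheme, both_strands=False)
            my_score = mine[0].raw_score if mine else 0
            assert my_score == int(oracle.score(q, s))

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(3)
        sub = random_bases(600, rng)
        q_fwd = sub[100:400]
        fwd = local_align(q_fwd, sub)[0]
        rev = local_align(revcomp(q_fwd), sub)[0]
        assert rev.raw_score == fwd.raw_score == 600
        assert rev.strand == "-" and fwd.strand == "+"
        assert (rev.s_start, rev.s_end) == (fwd.s_start, fwd.s_end) == (101, 400)
        assert rev.q_start <= rev.q_end

    def test_column_accounting_invariant(self, default_model):
        ref = random_bases(4000, np.random.default_rng(5))
        reads, _ = simulate_reads(ref, default_model, depth=3, seed=6)
        for r in reads:
            for a in local_align(r.bases, ref, query_id=r.id):
                assert a.identities + a.mismatches + a.gaps == a.aligned_columns
                assert 0 <= a.identity_pct <= 100
                assert a.q_start <= a.q_end
                assert 1 <= a.s_start <= a.s_end <= len(ref)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(7)
    return [ReferenceSeq(id=f"L{i}", bases=random_bases(800, rng),
                         role="marker_locus") for i in range(3)]


class TestMineLoci:

    def test_short_read_excluded_regardless_of_identity(self, panel):
        read = Read("short", panel[0].bases[:150], np.full(150, 20))
        res = mine_loci([read], panel)
        assert len(res.assignments) == 0

    def test_identity_threshold_is_strict(self, panel):
        """A read at exactly 80.0% identity is excluded; above 80 assigned."""
        src = panel[0].bases[:200]
        # 40 substitutions in the first 160 bp (one per 4-bp block), clean
        # 40 bp tail so seeding finds the alignment: 160/200 = 80.0%
        sub_pos = [i for i in range(160) if i % 4 == 2]
        mapping = {"A": "C", "C": "G", "G": "T", "T": "A"}
        exact80 = "".join(mapping[b] if i in set(sub_pos) else b
                          for i, b in enumerate(src))
        above80 = "".join(mapping[b] if i in set(sub_pos[1:]) else b
                          for i, b in enumerate(src))
        q = np.full(200, 20)
        res = mine_loci([Read("exact80", exact80, q)], panel, min_aln_len=50)
        assert len(res.assignments) == 0
        res = mine_loci([Read("above80", above80, q)], panel, min_aln_len=50)
        assert list(res.assignments.locus_id) == ["L0"]
        assert res.assignments.identity_pct.iloc[0] > 80.0

    def test_zero_error_assignments_match_truth_tally(self):
        """Error-free reads >=300 bp assign to the locus their truth
        interval overlaps most, whenever that overlap clears the
        alignment-length floor."""
        cfg = SampleConfig(seed=31, total_bases=80_000, genome_length=20_000,
                           proportions={"target_fungus": 1.0}, contaminants=())
        reads, _, refs = make_sample(cfg, ErrorModel(p_sub=0, p_ins=0, p_del=0))
        subset = [r for r in reads if len(r) >= 300]
        res = mine_loci(subset, refs.loci, min_read_len=300)
        assigned = dict(zip(res.assignments.read_id, res.assignments.locus_id))
        expected = {}
        for r in subset:
            best, best_ov = None, 0
            for l in refs.loci:
                lo, hi = refs.locus_intervals[l.id]
                ov = min(hi, r.truth.source_end) - max(lo, r.truth.source_start) + 1
                if ov > best_ov:
                    best, best_ov = l.id, ov
            if best is not None and best_ov >= 100:
                expected[r.id] = best
        assert assigned == expected

    def test_empty_panel_raises(self):
        with pytest.raises(ValueError):
            mine_loci([], [])


class TestMapGenome:
    def _toy_genome(self):
        bases = random_bases(3000, np.random.default_rng(11))
        genes = [GeneFeature("g1", 101, 500), GeneFeature("g2", 1001, 1400),
                 GeneFeature("g3", 2001, 2400)]
        return ReferenceSeq(id="chr1", bases=bases, features=genes)

    def test_no_passing_reads_gives_zero_coverage(self):
        genome = self._toy_genome()
        res = map_genome([], genome)
        assert res.coverage.totals["endogenous_bases"] == 0
        assert res.coverage.totals["genes_hit"] == 0
        assert not res.coverage.per_gene.covered.any()

    def test_gene_hits_from_constructed_unique_hits(self):
        """Reads overlapping exactly two of three genes -> genes_hit = 2."""
        genome = self._toy_genome()
        reads = [Read("r1", genome.bases[50:550], np.full(500, 20)),    # g1
                 Read("r2", genome.bases[900:1300], np.full(400, 20))]  # g2
        res = map_genome(reads, genome)
        assert res.coverage.totals["genes_hit"] == 2
        hit = set(res.coverage.per_gene.query("covered").gene_id)
        assert hit == {"g1", "g2"}

    def test_zero_error_gene_hits_match_truth_intervals(self):
        cfg = SampleConfig(seed=41, total_bases=100_000, genome_length=20_000,
                           gene_count=8, proportions={"target_fungus": 1.0},
                           contaminants=())
        reads, _, refs = make_sample(cfg, ErrorModel(p_sub=0, p_ins=0, p_del=0))
        res = map_genome(reads, refs.genome)
        expected_hit = set()
        for r in reads:
            if len(r) < 300:
                continue
            for g in refs.genome.features:
                if min(g.end, r.truth.source_end) >= max(g.start, r.truth.source_start):
                    expected_hit.add(g.id)
        assert set(res.coverage.per_gene.query("covered").gene_id) == expected_hit

    def test_coverage_conservation(self, small_sample):
        reads, _, refs = small_sample
        res = map_genome(reads, refs.genome)
        span_sum = sum(a.subject_span for a in res.unique_hits.values())
        assert res.coverage.totals["covered_bases"] <= span_sum
        assert res.coverage.totals["endogenous_bases"] == span_sum

    def test_filter_monotonicity(self, small_sample):
        reads, _, refs = small_sample
        loose = map_genome(reads, refs.genome, min_identity=80.0)
        for kw in (dict(min_identity=92.0), dict(min_aln_len=600),
                   dict(evalue_max=1e-30), dict(min_q=12.0)):
            tight = map_genome(reads, refs.genome, **kw)
            assert len(tight.alignments) <= len(loose.alignments)
            assert len(tight.unique_hits) <= len(loose.unique_hits)

    def test_unknown_chromosome_in_annotation_raises(self):
        genome = self._toy_genome()
        import pandas as pd
        genes = pd.DataFrame([{"feature_id": "gX", "seqid": "chr9",
                               "start": 1, "end": 10, "type": "gene",
                               "source": "t", "strand": "+"}])
        with pytest.raises(ValueError, match="unknown chromosome"):
            map_genome([], genome, genes)


def test_outfmt6_table_shape(small_sample):
    reads, _, refs = small_sample
    res = map_genome(reads[:40], refs.genome)
    df = alignments_to_outfmt6(res.alignments)
    assert list(df.columns) == ["qseqid", "sseqid", "pident", "length",
                                "mismatch", "gapopen", "qstart", "qend",
                                "sstart", "send", "evalue", "bitscore"]
    if len(df):
        assert (df.pident > 0).all() and (df.length > 0).all()
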