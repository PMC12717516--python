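"""Pileup construction, plurality consensus with deterministic tie rules,
polymorphism scoring, and the depth-accuracy benchmark machinery."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from taxoskim.align import local_align
from taxoskim.consensus import (Pileup, PileupColumn, build_pileup,
                                call_consensus, consensus_from_reads,
                                polymorphism_count, run_depth_benchmark)
from taxoskim.read_model import (ErrorModel, Read, add_flanks, revcomp,
                                 simulate_reads)
from taxoskim.sample import ReferenceSeq, random_bases


def _perfect_read(rid: str, bases: str) -> Read:
    return Read(rid, bases, np.full(len(bases), 20))


def _align_reads(reads, ref_bases):
    hits = []
    for r in reads:
        alns = local_align(r.bases, ref_bases, query_id=r.id)
        if alns:
            hits.append(alns[0])
    return hits


class TestBuildPileup:
    REF = random_bases(400, np.random.default_rng(2))

    def test_single_perfect_read_spanning_interval(self):
        read = _perfect_read("r1", self.REF)
        pile = build_pileup(_align_reads([read], self.REF), [read], self.REF,
                            target_interval=(1, 400))
        assert all(col.depth == 1 for col in pile.columns)
        for col, base in zip(pile.columns, self.REF):
            assert col.counts[base] == 1

    def test_disagreeing_reads_split_column(self):
        mutated = list(self.REF)
        pos = 200
        mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        reads = [_perfect_read("r1", self.REF), _perfect_read("r2", "".join(mutated))]
        pile = build_pileup(_align_reads(reads, self.REF), reads, self.REF,
                            target_interval=(1, 400))
        col = pile.columns[pos]
        nonzero = {b: c for b, c in col.counts.items() if c}
        assert sum(nonzero.values()) == 2 and len(nonzero) == 2

    def test_contributed_bases_match_independent_trace_walk(self, default_model):
        """Every aligned base/deletion lands in exactly one column: total
        pileup mass equals an independent per-alignment recount."""
        ref = random_bases(1000, np.random.default_rng(3))
        reads, _ = simulate_reads(ref, default_model, depth=5, seed=4)
        reads = reads[:50]
        hits = _align_reads(reads, ref)
        pile = build_pileup(hits, reads, ref, target_interval=(1, 1000))
        total_mass = sum(col.depth for col in pile.columns)
        expected = 0
        for a in hits:   # independent recount: subject-consuming columns
            sj = a.s_start
            for op in a.ops:
                if op in "=XD":
                    if 1 <= sj <= 1000:
                        expected += 1
                    sj += 1
        assert total_mass == expected

    def test_inconsistent_trace_rejected(self):
        read = _perfect_read("r1", self.REF[:100])
        a = _align_reads([read], self.REF)[0]
        a.ops = a.ops[:-10]   # truncated trace no longer reaches s_end
        with pytest.raises(ValueError, match="trace inconsistent"):
            build_pileup([a], [read], self.REF, target_interval=(1, 400))


def _column(ref_pos, a=0, c=0, g=0, t=0, d=0, ins=None, span=0):
    return PileupColumn(ref_pos, {"A": a, "C": c, "G": g, "T": t, "del": d},
                        insertions=ins or {}, spanning_next=span)


class TestCallConsensus:
    def test_base_tie_breaks_alphabetically(self):
        pile = Pileup([_column(1, a=5, c=5)], (1, 1))
        assert call_consensus(pile).sequence == "A"
        pile = Pileup([_column(1, c=5, t=5)], (1, 1))
        assert call_consensus(pile).sequence == "C"

    def test_deletion_loses_ties(self):
        pile = Pileup([_column(1, a=4, d=4)], (1, 1))
        assert call_consensus(pile).sequence == "A"
        pile = Pileup([_column(1, a=3, d=4)], (1, 1))
        assert call_consensus(pile).sequence == ""

    def test_insertion_needs_majority_of_spanning_reads(self):
        cols = [_column(1, a=4, ins={"GG": 3}, span=4), _column(2, c=4)]
        assert call_consensus(Pileup(cols, (1, 2))).sequence == "AGGC"
        cols = [_column(1, a=4, ins={"GG": 2}, span=4), _column(2, c=4)]
        assert call_consensus(Pileup(cols, (1, 2))).sequence == "AC"

    def test_uncovered_positions_tallied(self):
        cols = [_column(1, a=2), _column(2), _column(3, t=1)]
        res = call_consensus(Pileup(cols, (1, 3)))
        assert res.sequence == "AT"
        assert res.n_uncovered == 1


class TestPolymorphismCount:
    def test_identical_sequences(self):
        s = random_bases(500, np.random.default_rng(5))
        assert polymorphism_count(s, s) == (0, 0.0)

    def test_two_mismatches_one_deletion(self):
        truth = random_bases(1000, np.random.default_rng(6))
        cons = list(truth)
        cons[100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cons[100]]
        cons[500] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cons[500]]
        del cons[800]
        n_poly, err = polymorphism_count("".join(cons), truth)
        assert n_poly == 3
        assert err == pytest.approx(0.3)

    def test_counts_reproduce_optimal_global_score(self):
        """(match, mismatch, gap) counts recombine to the optimal global
        score of an exhaustive Needleman-Wunsch oracle on random pairs."""
        oracle = Align.PairwiseAligner()
        oracle.mode = "global"
        oracle.match_score, oracle.mismatch_score = 1, -1
        oracle.open_gap_score = oracle.extend_gap_score = -2
        rng = np.random.default_rng(7)
        from taxoskim.align import global_identity
        for _ in range(100):
            a = random_bases(int(rng.integers(5, 61)), rng)
            b = random_bases(int(rng.integers(5, 61)), rng)
            _, n_match, n_mis, n_gap = global_identity(a, b)
            assert n_match - n_mis - 2 * n_gap == int(oracle.score(a, b))

    def test_empty_consensus_counts_whole_truth(self):
        truth = "ACGTACGT"
        n_poly, err = polymorphism_count("", truth)
        assert n_poly == len(truth) and err == 100.0


@pytest.fixture(scope="module")
def ref_donor():
    rng = np.random.default_rng(8)
    return (ReferenceSeq(id="gene", bases=random_bases(800, rng)),
            ReferenceSeq(id="donor", bases=random_bases(3000, rng)))


class TestDepthBenchmark:

    def test_zero_error_consensus_exact_at_any_depth(self, ref_donor, zero_error_model):
        ref, donor = ref_donor
        df, summary = run_depth_benchmark(ref, donor, zero_error_model,
                                          depths=(1, 2, 10), replicates=1, seed=5)
        assert (df.error_pct == 0.0).all()
        assert (df.n_uncovered == 0).all()

    def test_error_order_invariance(self, ref_donor, default_model):
        ref, donor = ref_donor
        aug = add_flanks(ref, donor, 100)
        reads, _ = simulate_reads(aug, default_model, depth=8, seed=9,
                                  min_len_quantile=0.95)
        c1 = consensus_from_reads(reads, aug)
        c2 = consensus_from_reads(list(reversed(reads)), aug)
        assert c1.sequence == c2.sequence
        assert c1.n_uncovered == c2.n_uncovered

    def test_error_decreases_with_depth(self, ref_donor, default_model):
        """Paired-seed contrast: mean error at depth d exceeds mean error
        at 4d (d in {2, 5}, 5 replicates) up to a 0.1-point tolerance."""
        ref, donor = ref_donor
        df, _ = run_depth_benchmark(ref, donor, default_model,
                                    depths=(2, 5, 8, 20), replicates=5, seed=13)
        means = df.groupby("depth").error_pct.mean()
        assert means[2] >= means[8] - 0.1
        assert means[5] >= means[20] - 0.1
        assert means[2] > means[20]

    def test_trial_table_is_deterministic(self, ref_donor, default_model):
        ref, donor = ref_donor
        df1, _ = run_depth_benchmark(ref, donor, default_model,
                                     depths=(5,), replicates=2, seed=21)
        df2, _ = run_depth_benchmark(ref, donor, default_model,
                                     depths=(5,), replicates=2, seed=21)
        assert df1.equals(df2)
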