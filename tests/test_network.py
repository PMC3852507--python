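"""Condition-network construction: correlation filter, Jaccard scoring,
randomization significance, edge thresholding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import overlap_tail_table
from mran.io import ExpressionMatrix, TargetMap
from mran.network import (build_condition_mran, inverse_pair_filter,
                          jaccard_overlap, overlap_pvalue,
                          pearson_correlation)


class TestPearson:
    def test_perfect_anticorrelation(self):
        assert pearson_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 2, 3], [2, 2, 2])

    def test_short_vectors_error(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [2, 1])


def _em(condition, rows, samples):
    return ExpressionMatrix(condition, pd.DataFrame(
        {s: [rows[f][i] for f in rows] for i, s in enumerate(samples)},
        index=list(rows)))


class TestInversePairFilter:
    samples = ["s1", "s2", "s3", "s4"]

    def test_anticorrelated_pair_retained(self):
        mir = _em("c", {"m1": [1, 2, 3, 4]}, self.samples)
        mrna = _em("c", {"gA": [4, 3, 2, 1]}, self.samples)
        res = inverse_pair_filter(mir, mrna, TargetMap({"m1": frozenset({"gA"})}))
        assert len(res.pairs) == 1
        assert res.pairs[0].r == pytest.approx(-1.0)
        assert res.cond_targets == {"m1": frozenset({"gA"})}

    def test_positively_correlated_pair_dropped(self):
        mir = _em("c", {"m1": [1, 2, 3, 4]}, self.samples)
        mrna = _em("c", {"gA": [1, 2, 3, 4]}, self.samples)
        res = inverse_pair_filter(mir, mrna, TargetMap({"m1": frozenset({"gA"})}))
        assert res.pairs == [] and res.cond_targets == {}

    def test_unmeasured_gene_skipped_and_counted(self):
        mir = _em("c", {"m1": [1, 2, 3, 4]}, self.samples)
        mrna = _em("c", {"gB": [4, 3, 2, 1]}, self.samples)
        res = inverse_pair_filter(mir, mrna, TargetMap({"m1": frozenset({"gA"})}))
        assert res.pairs == []
        assert res.n_skipped_unmeasured == 1

    def test_no_overlapping_samples_errors(self):
        mir = _em("c", {"m1": [1, 2, 3]}, ["a1", "a2", "a3"])
        mrna = _em("c", {"gA": [3, 2, 1]}, ["b1", "b2", "b3"])
        with pytest.raises(ValueError, match="overlapping samples"):
            inverse_pair_filter(mir, mrna, TargetMap({"m1": frozenset({"gA"})}))

    def test_case_insensitive_id_join(self):
        mir = _em("c", {"MIR-1": [1, 2, 3, 4]}, self.samples)
        mrna = _em("c", {"GeneA": [4, 3, 2, 1]}, self.samples)
        res = inverse_pair_filter(mir, mrna,
                                  TargetMap({"mir-1": frozenset({"genea"})}))
        assert len(res.pairs) == 1


class TestJaccard:
    def test_half_overlap(self):
        assert jaccard_overlap({"A", "B", "C"}, {"B", "C", "D"}) == 0.5

    def test_identical_sets(self):
        assert jaccard_overlap({"A", "B"}, {"A", "B"}) == 1.0

    def test_disjoint(self):
        assert jaccard_overlap({"A"}, {"B"}) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            jaccard_overlap(set(), {"A"})

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)))
    def test_symmetric_bounded_and_extremes(self, a, b):
        if not a or not b:
            return
        t = jaccard_overlap(a, b)
        assert t == jaccard_overlap(b, a)
        assert 0.0 <= t <= 1.0
        assert (t == 1.0) == (a == b)
        assert (t == 0.0) == (not a & b)


class TestOverlapPvalue:
    def test_exact_example(self):
        assert overlap_pvalue(4, 5, 3, 10) == pytest.approx(66 / 252,
                                                            abs=1e-12)

    def test_zero_overlap_tail_is_one(self):
        assert overlap_pvalue(4, 5, 0, 10) == 1.0

    def test_permutation_close_to_exact(self):
        exact = overlap_pvalue(4, 5, 3, 10)
        perm = overlap_pvalue(4, 5, 3, 10, method="permutation",
                              n_perm=10000, rng_seed=11)
        se = np.sqrt(exact * (1 - exact) / 10000)
        assert abs(perm - exact) < 3 * se + 2 / 10001

    def test_matches_enumeration_small_universes(self):
        for N in (5, 8, 10):
            for m1 in (1, 3, N - 1):
                for m2 in (2, N // 2):
                    tails = overlap_tail_table(m1, m2, N)
                    for c, expected in enumerate(tails):
                        if N >= m1 + m2 - c:
                            got = overlap_pvalue(m1, m2, c, N)
                            assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_overlap(self):
        ps = [overlap_pvalue(6, 7, c, 20) for c in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_overlap_errors(self):
        with pytest.raises(ValueError):
            overlap_pvalue(3, 4, 4, 10)

    def test_too_small_universe_errors(self):
        with pytest.raises(ValueError):
            overlap_pvalue(5, 5, 0, 8)


class TestBuildConditionMran:
    def test_identical_target_sets_linked(self):
        genes = frozenset(f"g{i}" for i in range(10))
        net = build_condition_mran({"m1": genes, "m2": genes}, "c",
                                   universe=50)
        assert net.graph.has_edge("m1", "m2")
        d = net.graph.edges["m1", "m2"]
        assert d["t"] == 1.0
        assert d["p"] < 0.05
        assert d["weight"] == pytest.approx(1 - d["p"])

    def test_disjoint_targets_unlinked(self):
        net = build_condition_mran(
            {"m1": frozenset({"g1", "g2"}), "m2": frozenset({"g3", "g4"})},
            "c")
        assert net.graph.number_of_edges() == 0
        assert net.graph.number_of_nodes() == 2

    def test_single_mirna(self):
        net = build_condition_mran({"m1": frozenset({"g1"})}, "c")
        assert net.n_nodes == 1 and net.n_edges == 0

    def test_edges_shrink_as_alpha_decreases(self, rng):
        genes = [f"g{i}" for i in range(30)]
        cond = {f"m{i}": frozenset(rng.choice(genes, size=8, replace=False))
                for i in range(12)}
        alphas = [0.5, 0.2, 0.05, 0.01]
        edge_sets = [set(build_condition_mran(cond, "c", alpha_edge=a)
                         .graph.edges) for a in alphas]
        for bigger, smaller in zip(edge_sets, edge_sets[1:]):
            assert smaller <= bigger

    def test_bad_alpha_errors(self):
        with pytest.raises(ValueError):
            build_condition_mran({}, "c", alpha_edge=1.5)
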