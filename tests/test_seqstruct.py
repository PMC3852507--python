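"""Sequence identity, structure parsing, tree edit distance, folding and
the within/between/random similarity comparison."""

import numpy as np
import pytest

from oracles import max_pairs_enum, nw_best_score, ranksum_enum, ted_naive
from mran.io import HairpinRecord
from mran.seqstruct import (DotBracketError, base_pair_distance,
                            compare_similarity_distributions, extract_seed,
                            nussinov_fold, pairwise_identity,
                            parse_dotbracket, ranksum_test,
                            tree_edit_distance, _needleman_wunsch)


class TestSeed:
    def test_default_window(self):
        assert extract_seed("ACGUACGUACGUACGUACGUAC") == "CGUACGU"

    def test_shifted_window(self):
        assert extract_seed("ACGUACGUACGUACGUACGUAC", 1, 7) == "ACGUACG"

    def test_window_beyond_sequence_errors(self):
        with pytest.raises(ValueError):
            extract_seed("ACGUAC", 2, 8)


class TestIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGUACGU", "ACGUACGU") == 1.0

    def test_totally_different(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_one_mismatch(self):
        assert pairwise_identity("ACGU", "ACGA") == 0.75

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGU")

    def test_symmetric(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(20):
            a = "".join(rng.choice(bases, size=int(rng.integers(1, 9))))
            b = "".join(rng.choice(bases, size=int(rng.integers(1, 9))))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_alignment_score_matches_exhaustive_search(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(40):
            a = "".join(rng.choice(bases, size=int(rng.integers(1, 6))))
            b = "".join(rng.choice(bases, size=int(rng.integers(1, 6))))
            score, _, _ = _needleman_wunsch(a, b, 1.0, 0.0, -1.0)
            assert score == pytest.approx(nw_best_score(a, b))


class TestDotBracket:
    def test_nested_pairs(self):
        _, pairs = parse_dotbracket("((..))")
        assert pairs == {(1, 6), (2, 5)}

    def test_unpaired_only(self):
        tree, pairs = parse_dotbracket("....")
        assert pairs == set()
        assert tree.size == 5  # root + 4 leaves

    def test_unbalanced_open_reports_end_position(self):
        with pytest.raises(DotBracketError) as err:
            parse_dotbracket("((.")
        assert err.value.position == 3

    def test_unbalanced_close_reports_its_position(self):
        with pytest.raises(DotBracketError) as err:
            parse_dotbracket(".)(")
        assert err.value.position == 2

    def test_roundtrip_through_tree(self):
        for s in ["((..))", "(.(...).)", "...", "", "(((...)))"]:
            tree, _ = parse_dotbracket(s)
            assert tree.to_dotbracket() == s


class TestBasePairDistance:
    def test_identical(self):
        assert base_pair_distance("((..))", "((..))") == 0

    def test_one_pair_difference(self):
        assert base_pair_distance("((..))", "(....)") == 1

    def test_unequal_length_errors(self):
        with pytest.raises(ValueError):
            base_pair_distance("(..)", "((..))")

    def test_bounded_by_twice_denser_structure(self, rng):
        structures = ["((..))", "(....)", "((((...))))", "...(...)...",
                      "(.(...).)"]
        for s1 in structures:
            for s2 in structures:
                if len(s1) != len(s2):
                    continue
                _, p1 = parse_dotbracket(s1)
                _, p2 = parse_dotbracket(s2)
                assert base_pair_distance(s1, s2) <= 2 * max(len(p1), len(p2))


def _all_small_dotbrackets(max_len):
    from itertools import product
    out = []
    for n in range(0, max_len + 1):
        for chars in product("().", repeat=n):
            s = "".join(chars)
            depth = 0
            ok = True
            for ch in s:
                depth += 1 if ch == "(" else (-1 if ch == ")" else 0)
                if depth < 0:
                    ok = False
                    break
            if ok and depth == 0:
                out.append(s)
    return out


class TestTreeEditDistance:
    def test_identical_trees(self):
        t, _ = parse_dotbracket("((..))")
        assert tree_edit_distance(t, t) == 0

    def test_insert_one_leaf(self):
        t1, _ = parse_dotbracket("(..)")
        t2, _ = parse_dotbracket("(...)")
        assert tree_edit_distance(t1, t2) == 1

    def test_delete_pair_insert_leaves(self):
        t1, _ = parse_dotbracket("((..))")
        t2, _ = parse_dotbracket("(....)")
        assert tree_edit_distance(t1, t2) == 3

    def test_matches_naive_forest_recursion_exhaustively(self):
        structs = _all_small_dotbrackets(6)
        trees = [parse_dotbracket(s)[0] for s in structs]
        for i, t1 in enumerate(trees):
            for t2 in trees[i:]:
                assert tree_edit_distance(t1, t2) == ted_naive(t1, t2)

    def test_metric_axioms_on_random_structures(self, rng):
        structs = [nussinov_fold(_random_rna(rng, 24)) for _ in range(18)]
        trees = [parse_dotbracket(s)[0] for s in structs]
        n = len(trees)
        d = [[tree_edit_distance(trees[i], trees[j]) for j in range(n)]
             for i in range(n)]
        for i in range(n):
            assert d[i][i] == 0
            for j in range(n):
                assert d[i][j] == d[j][i]
        for _ in range(200):
            i, j, k = rng.integers(0, n, size=3)
            assert d[i][j] <= d[i][k] + d[k][j]


def _random_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])


class TestNussinov:
    def test_hairpin_example(self):
        assert nussinov_fold("GCGAAACGC") == "(((...)))"

    def test_unpairable_sequence(self):
        assert nussinov_fold("AAAA") == "...."

    def test_too_short_for_loop(self):
        assert nussinov_fold("GC") == ".."

    def test_non_rna_errors(self):
        with pytest.raises(ValueError):
            nussinov_fold("ACGX")

    def test_dna_input_transliterated(self):
        assert nussinov_fold("GCGTTTCGC") == nussinov_fold("GCGUUUCGC")

    def test_pair_count_matches_enumeration(self, rng):
        for n in range(4, 13):
            for _ in range(6):
                seq = _random_rna(rng, n)
                struct = nussinov_fold(seq)
                _, pairs = parse_dotbracket(struct)
                assert len(pairs) == max_pairs_enum(seq)
                # structure validity: canonical pairs and loop constraint
                for (i, j) in pairs:
                    assert seq[i - 1] + seq[j - 1] in {
                        "AU", "UA", "GC", "CG", "GU", "UG"}
                    assert j - i - 1 >= 3

    def test_deterministic(self, rng):
        seq = _random_rna(rng, 40)
        assert nussinov_fold(seq) == nussinov_fold(seq)


class TestRanksum:
    def test_separated_samples_two_sided(self):
        assert ranksum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_separated_samples_one_sided(self):
        assert ranksum_test([1, 2, 3], [4, 5, 6], "less") == pytest.approx(0.05)

    def test_identical_multisets_near_one(self):
        assert ranksum_test([1, 2, 3], [1, 2, 3]) >= 0.99

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])

    def test_exact_branch_matches_enumeration(self, rng):
        for n in range(1, 6):
            for m in range(1, 6):
                vals = rng.permutation(np.arange(n + m, dtype=float) * 1.7)
                x, y = list(vals[:n]), list(vals[n:])
                for alt in ("two_sided", "less", "greater"):
                    assert ranksum_test(x, y, alt) == pytest.approx(
                        ranksum_enum(x, y, alt), abs=1e-12)


def _record(mid, precursor, struct, mature_len=8):
    return HairpinRecord(mid, precursor[:mature_len], precursor, struct, 1,
                         mature_len)


class TestCompareDistributions:
    def _identical_records(self, n):
        return [_record(f"m{i}", "GCGCAAAAGCGC", "((((....))))")
                for i in range(n)]

    def test_all_identical_records_uninformative(self):
        recs = self._identical_records(8)
        cmms = [[f"m{i}" for i in range(4)], [f"m{i}" for i in range(4, 8)]]
        rep = compare_similarity_distributions(cmms, recs, "precursor_struct",
                                               rng_seed=1)
        assert rep.p_within_vs_between >= 0.99
        assert rep.p_within_vs_random >= 0.99

    def test_single_module_between_absent(self):
        recs = self._identical_records(6)
        rep = compare_similarity_distributions([["m0", "m1", "m2"]], recs,
                                               "mature", rng_seed=1)
        assert rep.between == []
        assert rep.p_within_vs_between is None
        assert rep.p_within_vs_random is not None

    def test_missing_record_named(self):
        recs = self._identical_records(3)
        with pytest.raises(KeyError, match="ghost"):
            compare_similarity_distributions([["m0", "ghost"]], recs, "seed")

    def test_unknown_layer_errors(self):
        with pytest.raises(ValueError):
            compare_similarity_distributions([], [], "tertiary")

    def test_structure_families_more_similar_within(self):
        from mran.simulate import make_truth, simulate_hairpins
        truth = make_truth(rng_seed=5)
        rng = np.random.default_rng(5)
        ids = [f"mir-{i:04d}" for i in range(1, 36)]
        recs = simulate_hairpins(ids, truth, rng)
        rep = compare_similarity_distributions(truth.groups, recs,
                                               "precursor_struct", rng_seed=5)
        assert rep.p_within_vs_between < 0.01
        assert rep.p_within_vs_random < 0.01
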