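"""Global network merging and dense-module (MCODE) extraction."""

import networkx as nx
import pytest

from conftest import random_graph
from oracles import core_numbers_brute
from mran.mcode import (annotate_modules, core_decomposition,
                        mcode_complexes, merge_condition_mrans,
                        vertex_weight)
from mran.network import ConditionMRAN


def cnet(condition, edges, nodes=(), cond_targets=None):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, t=0.5, p=0.01, weight=0.99)
    return ConditionMRAN(condition, g, cond_targets or {})


class TestMerge:
    def test_shared_edge_gets_two_records(self):
        merged = merge_condition_mrans([cnet("c1", [("a", "b")]),
                                        cnet("c2", [("a", "b")])])
        assert merged.graph.number_of_edges() == 1
        assert len(merged.graph.edges["a", "b"]["records"]) == 2
        assert merged.conditions == ["c1", "c2"]

    def test_single_net_is_identity(self):
        net = cnet("c1", [("a", "b"), ("b", "c")], nodes=["lonely"])
        merged = merge_condition_mrans([net])
        assert set(merged.graph.nodes) == set(net.graph.nodes)
        assert set(merged.graph.edges) == set(net.graph.edges)

    def test_disjoint_nets_union(self):
        merged = merge_condition_mrans([cnet("c1", [("a", "b")]),
                                        cnet("c2", [("x", "y")])])
        assert set(merged.graph.nodes) == {"a", "b", "x", "y"}
        assert merged.graph.number_of_edges() == 2

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            merge_condition_mrans([])


class TestCoreDecomposition:
    def test_complete_graph(self):
        assert core_decomposition(nx.complete_graph(4)) == {i: 3
                                                            for i in range(4)}

    def test_tree_cores_at_most_one(self):
        tree = nx.balanced_tree(2, 3)
        assert max(core_decomposition(tree).values()) <= 1

    def test_empty_graph(self):
        assert core_decomposition(nx.Graph()) == {}

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            g = random_graph(rng, n, float(rng.uniform(0.2, 0.8)))
            expected = core_numbers_brute(list(g.edges), list(g.nodes))
            assert core_decomposition(g) == expected


class TestVertexWeight:
    def test_triangle_vertex(self):
        assert vertex_weight(nx.complete_graph(3), 0) == pytest.approx(2.0)

    def test_single_edge_endpoint(self):
        g = nx.Graph([("a", "b")])
        assert vertex_weight(g, "a") == pytest.approx(1.0)

    def test_isolated_vertex(self):
        g = nx.Graph()
        g.add_node("a")
        assert vertex_weight(g, "a") == 0.0

    def test_absent_vertex_errors(self):
        with pytest.raises(KeyError):
            vertex_weight(nx.Graph(), "ghost")


def two_cliques_with_path():
    g = nx.Graph()
    k5a = [f"a{i}" for i in range(5)]
    k5b = [f"b{i}" for i in range(5)]
    for clique in (k5a, k5b):
        g.add_edges_from((u, v) for i, u in enumerate(clique)
                         for v in clique[i + 1:])
    path = ["a0", "p0", "p1", "p2", "b0"]
    g.add_edges_from(zip(path, path[1:]))
    return g, frozenset(k5a), frozenset(k5b)


class TestMcode:
    def test_recovers_planted_cliques_exactly(self):
        g, k5a, k5b = two_cliques_with_path()
        modules = mcode_complexes(g)
        assert {m.mirnas for m in modules} == {k5a, k5b}

    def test_tree_yields_no_modules(self):
        assert mcode_complexes(nx.balanced_tree(3, 3)) == []

    def test_triangle_is_one_module(self):
        modules = mcode_complexes(nx.complete_graph(3))
        assert len(modules) == 1
        assert modules[0].mirnas == frozenset({0, 1, 2})
        assert modules[0].score == pytest.approx(3.0)

    def test_every_module_has_min_degree_two(self, rng):
        for _ in range(20):
            g = random_graph(rng, 18, 0.22)
            for m in mcode_complexes(g):
                sub = g.subgraph(m.mirnas)
                assert min(d for _, d in sub.degree()) >= 2

    def test_invariant_under_relabeling(self, rng):
        g = random_graph(rng, 16, 0.3)
        mapping = {v: f"w{i}" for i, v in
                   enumerate(sorted(g.nodes, key=lambda v: hash(v)))}
        h = nx.relabel_nodes(g, mapping)
        mods_g = {frozenset(mapping[v] for v in m.mirnas)
                  for m in mcode_complexes(g)}
        mods_h = {m.mirnas for m in mcode_complexes(h)}
        assert mods_g == mods_h

    def test_ranked_by_score_descending(self, rng):
        g = random_graph(rng, 25, 0.25)
        modules = mcode_complexes(g)
        scores = [m.score for m in modules]
        assert scores == sorted(scores, reverse=True)
        assert [m.module_id for m in modules] == list(
            range(1, len(modules) + 1))

    def test_bad_vwp_errors(self):
        with pytest.raises(ValueError):
            mcode_complexes(nx.Graph(), vwp=1.0)


class TestAnnotate:
    def _nets(self):
        t1 = {m: frozenset(f"g{i}" for i in range(100))
              for m in ("a", "b")}
        return [cnet("c1", [("a", "b")], cond_targets=t1)]

    def test_identical_sets_union(self):
        nets = self._nets()
        from mran.mcode import CMM
        cmm = CMM(module_id=1, mirnas=frozenset({"a", "b"}),
                  seed_vertex="a", score=1.0, density=1.0)
        out = annotate_modules([cmm], nets)
        assert len(out[0].target_union) == 100
        assert out[0].links == 1
        assert out[0].conditions == frozenset({"c1"})

    def test_disjoint_member_sets_add(self):
        from mran.mcode import CMM
        targets = {m: frozenset(f"{m}-g{i}" for i in range(10))
                   for m in ("a", "b", "c")}
        net = cnet("c1", [("a", "b"), ("b", "c"), ("a", "c")],
                   cond_targets=targets)
        cmm = CMM(module_id=1, mirnas=frozenset({"a", "b", "c"}),
                  seed_vertex="a", score=1.0, density=1.0)
        out = annotate_modules([cmm], [net])
        assert len(out[0].target_union) == 30

    def test_union_spans_contributing_conditions(self):
        from mran.mcode import CMM
        n1 = cnet("c1", [("a", "b")],
                  cond_targets={"a": frozenset({"g1"}), "b": frozenset({"g2"})})
        n2 = cnet("c2", [("a", "b")],
                  cond_targets={"a": frozenset({"g3"}), "b": frozenset({"g4"})})
        cmm = CMM(module_id=1, mirnas=frozenset({"a", "b"}),
                  seed_vertex="a", score=1.0, density=1.0)
        out = annotate_modules([cmm], [n1, n2])
        assert out[0].target_union == frozenset({"g1", "g2", "g3", "g4"})

    def test_unknown_member_errors(self):
        from mran.mcode import CMM
        cmm = CMM(module_id=1, mirnas=frozenset({"ghost", "a"}),
                  seed_vertex="a", score=1.0, density=1.0)
        with pytest.raises(KeyError, match="ghost"):
            annotate_modules([cmm], self._nets())
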