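"""Module-level hypergraph construction, weights and sub-hypergraphs."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lahyper as lh
from lahyper.grouping import ModuleAssignment


def _random_assignment(n_genes, modules, rng, multi_prob=0.0):
    membership = {}
    for i in range(n_genes):
        mods = [rng.choice(modules)]
        if multi_prob and rng.random() < multi_prob:
            extra = rng.choice([m for m in modules if m != mods[0]])
            mods.append(extra)
        membership[f"g{i}"] = sorted(set(mods))
    return ModuleAssignment(mode="supervised", membership=membership)


class TestLift:
    def test_singleton_memberships(self):
        asg = ModuleAssignment(
            mode="supervised", membership={"x": ["a"], "y": ["a"], "z": ["b"]}
        )
        lifted, dropped = lh.lift_triplets([("x", "y", "z")], asg)
        assert lifted == [("a", "a", "b")]
        assert dropped == 0

    def test_multi_membership_duplicates(self):
        asg = ModuleAssignment(
            mode="supervised",
            membership={"x": ["a", "b"], "y": ["c"], "z": ["d"]},
        )
        lifted, _ = lh.lift_triplets([("x", "y", "z")], asg)
        assert sorted(lifted) == [("a", "c", "d"), ("b", "c", "d")]

    def test_unassigned_gene_discards_triplet(self):
        asg = ModuleAssignment(mode="supervised", membership={"x": ["a"], "y": ["a"]},
                               dropped=["z"])
        lifted, dropped = lh.lift_triplets([("x", "y", "z"), ("x", "y", "x2")], asg)
        assert lifted == [] and dropped == 2

    def test_matches_bruteforce_expansion(self):
        rng = np.random.default_rng(31)
        asg = _random_assignment(20, ["a", "b", "c", "d"], rng, multi_prob=0.4)
        triplets = [
            tuple(f"g{v}" for v in sorted(rng.choice(20, 3, replace=False)))
            for _ in range(30)
        ]
        lifted, _ = lh.lift_triplets(triplets, asg)
        expect = []
        for gs in triplets:
            for combo in itertools.product(*(asg.membership[g] for g in gs)):
                expect.append(tuple(sorted(combo)))
        assert Counter(lifted) == Counter(expect)


class TestEdgeTypeAndExpectation:
    @settings(derandomize=True, max_examples=60)
    @given(st.tuples(st.sampled_from("abc"), st.sampled_from("abc"), st.sampled_from("abc")))
    def test_edge_type_is_distinct_label_count(self, mods):
        assert lh.classify_edge_type(mods) == len(set(mods))

    @pytest.mark.parametrize("with_replacement", [False, True])
    def test_probabilities_sum_to_one_over_all_multisets(self, with_replacement):
        sizes = {"a": 4, "b": 7, "c": 2, "d": 10}
        total = 0.0
        for mods in itertools.combinations_with_replacement(sorted(sizes), 3):
            total += lh.multiset_probability(mods, sizes, with_replacement)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_expected_count_by_direct_enumeration(self):
        # 2 modules of 3 genes each: of the C(6,3)=20 gene triples,
        # exactly C(3,2)*C(3,1)=9 carry labels {a,a,b} -> p=0.45, expected 9 at T=20
        sizes = {"a": 3, "b": 3}
        p = lh.multiset_probability(("a", "a", "b"), sizes, with_replacement=False)
        assert p == pytest.approx(0.45, abs=1e-12)
        assert lh.expected_count(("a", "a", "b"), sizes, 20) == pytest.approx(9.0)
        labels = ["a"] * 3 + ["b"] * 3
        hits = sum(
            1
            for combo in itertools.combinations(range(6), 3)
            if sorted(labels[i] for i in combo) == ["a", "a", "b"]
        )
        assert hits / 20 == pytest.approx(p)

    def test_zero_size_module_rejected(self):
        with pytest.raises(ValueError):
            lh.multiset_probability(("a", "a", "b"), {"a": 3, "b": 0}, False)


class TestBuildAndThreshold:
    def test_aggregation_counts(self):
        asg = ModuleAssignment(
            mode="supervised",
            membership={f"g{i}": [m] for i, m in enumerate("aaabbbccc")},
        )
        lifted = [("a", "b", "c"), ("a", "b", "c"), ("a", "a", "b")]
        g = lh.build_hypergraph(lifted, asg)
        lookup = g.edge_lookup()
        assert lookup[("a", "b", "c")].count == 2
        assert lookup[("a", "a", "b")].count == 1
        assert lookup[("a", "b", "c")].edge_type == 3
        assert lookup[("a", "a", "b")].edge_type == 2
        assert sum(e.count for e in g.edges) == g.total_lifted == 3

    def test_aggregation_matches_sort_and_group_oracle(self):
        rng = np.random.default_rng(32)
        mods = ["a", "b", "c", "d", "e"]
        lifted = [tuple(sorted(rng.choice(mods, 3))) for _ in range(200)]
        asg = ModuleAssignment(
            mode="supervised",
            membership={f"g{i}": [mods[i % 5]] for i in range(25)},
        )
        g = lh.build_hypergraph(lifted, asg)
        oracle = Counter(lifted)
        assert {e.modules: e.count for e in g.edges} == dict(oracle)

    def test_empty_lifted_is_error(self):
        asg = ModuleAssignment(mode="supervised", membership={"g": ["a"]})
        with pytest.raises(ValueError):
            lh.build_hypergraph([], asg)

    def test_threshold_zero_is_identity_and_median_degree(self):
        rng = np.random.default_rng(33)
        asg = _random_assignment(30, ["a", "b", "c"], rng)
        lifted = [
            tuple(sorted(rng.choice(["a", "b", "c"], 3))) for _ in range(100)
        ]
        g = lh.build_hypergraph(lifted, asg)
        t0 = lh.threshold_edges(g, 0.0)
        assert {e.modules for e in t0.edges} == {e.modules for e in g.edges}
        deg = lh.vertex_degrees(t0)
        assert t0.median_degree == float(np.median([d for d in deg.values() if d > 0]))

    def test_threshold_drops_isolated_vertices(self):
        asg = ModuleAssignment(
            mode="supervised",
            membership={"g0": ["a"], "g1": ["a"], "g2": ["a"], "g3": ["b"]},
        )
        lifted = [("a", "a", "a")] * 5 + [("a", "a", "b")]
        g = lh.build_hypergraph(lifted, asg)
        lookup = g.edge_lookup()
        cut = (lookup[("a", "a", "b")].fold_change + lookup[("a", "a", "a")].fold_change) / 2
        lo, hi = sorted([lookup[("a", "a", "b")].fold_change, lookup[("a", "a", "a")].fold_change])
        t = lh.threshold_edges(g, (lo + hi) / 2)
        assert len(t.edges) == 1
        kept = t.edges[0]
        assert set(t.vertices) == set(kept.modules)

    def test_suggest_threshold_matches_linear_scan(self):
        rng = np.random.default_rng(34)
        asg = _random_assignment(40, list("abcdef"), rng)
        lifted = [tuple(sorted(rng.choice(list("abcdef"), 3))) for _ in range(500)]
        g = lh.build_hypergraph(lifted, asg)
        target = 2.0
        t = lh.suggest_threshold(g, target)
        assert t is not None
        med = lh.threshold_edges(g, t).median_degree
        assert med is not None and med <= target
        # no smaller candidate achieves the target
        for cand in sorted({0.0, *(e.fold_change for e in g.edges)}):
            if cand >= t:
                break
            med_c = lh.threshold_edges(g, cand).median_degree
            assert med_c is None or med_c > target


class TestSubHypergraphs:
    @pytest.fixture()
    def random_graph(self):
        rng = np.random.default_rng(35)
        mods = list("abcdefgh")
        asg = _random_assignment(80, mods, rng)
        lifted = [tuple(sorted(rng.choice(mods, 3))) for _ in range(400)]
        return lh.build_hypergraph(lifted, asg)

    def test_ego_matches_bruteforce_filter(self, random_graph):
        for v in ("a", "d", "h"):
            sub = lh.ego_subhypergraph(random_graph, v)
            expect = [e for e in random_graph.edges if v in e.modules]
            assert sub.edges == expect
            assert set(sub.vertices) == {v} | {m for e in expect for m in e.modules}

    def test_ego_unknown_vertex(self, random_graph):
        with pytest.raises(KeyError):
            lh.ego_subhypergraph(random_graph, "nope")

    def test_top_k_whole_graph_when_k_large(self, random_graph):
        sub = lh.top_k_subhypergraph(random_graph, 100)
        assert set(sub.vertices) == set(random_graph.vertices)
        assert sub.edges == random_graph.edges

    def test_top_k_matches_oracle(self, random_graph):
        deg = lh.vertex_degrees(random_graph)
        for k in (1, 3, 5):
            sub = lh.top_k_subhypergraph(random_graph, k)
            top = set(sorted(deg, key=lambda v: (-deg[v], v))[:k])
            assert set(sub.vertices) == top
            assert sub.edges == [
                e for e in random_graph.edges if set(e.modules) <= top
            ]

    def test_gene_level_counts_match_parent_edge(self):
        rng = np.random.default_rng(36)
        asg = _random_assignment(30, ["a", "b", "c"], rng, multi_prob=0.3)
        triplets = [
            tuple(f"g{v}" for v in sorted(rng.choice(30, 3, replace=False)))
            for _ in range(60)
        ]
        lifted, _ = lh.lift_triplets(triplets, asg)
        graph = lh.build_hypergraph(lifted, asg)
        for edge in graph.edges[:5]:
            sizes, gene_edges = lh.gene_level_subhypergraph(triplets, asg, edge.modules)
            assert len(gene_edges) == edge.count
            # vertex size = number of incident gene-level hyperedges
            for g, s in sizes.items():
                assert s == sum(1 for ge in gene_edges if g in ge)

    def test_gene_level_missing_triple(self):
        asg = ModuleAssignment(mode="supervised", membership={"x": ["a"], "y": ["a"], "z": ["a"]})
        with pytest.raises(KeyError):
            lh.gene_level_subhypergraph([("x", "y", "z")], asg, ("a", "a", "b"))


class TestExports:
    def test_clique_expansion_structure(self):
        asg = ModuleAssignment(
            mode="supervised",
            membership={"g0": ["a"], "g1": ["a"], "g2": ["a"], "g3": ["b"], "g4": ["c"]},
        )
        lifted = [("a", "a", "a"), ("a", "b", "c"), ("a", "a", "b")]
        g = lh.build_hypergraph(lifted, asg)
        G = lh.clique_expansion(g)
        assert G.has_edge("a", "a")  # type-1 self-loop
        assert G.has_edge("a", "b") and G.has_edge("b", "c") and G.has_edge("a", "c")
        assert G.nodes["a"]["size"] == 3
        assert G.nodes["a"]["degree"] == 3

    def test_graphml_and_tsv_roundtrip(self, tmp_path):
        import networkx as nx

        asg = ModuleAssignment(
            mode="supervised", membership={f"g{i}": ["ab"[i % 2]] for i in range(6)}
        )
        lifted = [("a", "a", "b")] * 4 + [("a", "b", "b")]
        g = lh.build_hypergraph(lifted, asg)
        lh.hypergraph.write_hyperedges_tsv(g, tmp_path / "edges.tsv")
        lines = (tmp_path / "edges.tsv").read_text().strip().split("\n")
        assert len(lines) == 1 + len(g.edges)
        lh.hypergraph.write_graphml(g, tmp_path / "g.graphml")
        G = nx.read_graphml(tmp_path / "g.graphml")
        assert set(G.nodes) == {"a", "b"}


class TestFoldChangeCalibration:
    def test_uniform_random_assignment_mean_fold_change_near_one(self):
        rng = np.random.default_rng(37)
        modules = ["m1", "m2", "m3", "m4"]
        membership = {f"g{i}": [modules[i % 4]] for i in range(100)}
        asg = ModuleAssignment(mode="supervised", membership=membership)
        gene_ids = list(membership)
        lifted = []
        for _ in range(10_000):
            picks = rng.choice(100, 3, replace=False)
            lifted.append(tuple(sorted(membership[gene_ids[p]][0] for p in picks)))
        g = lh.build_hypergraph(lifted, asg)
        mean_fc = float(np.mean([e.fold_change for e in g.edges]))
        assert mean_fc == pytest.approx(1.0, abs=0.05)
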