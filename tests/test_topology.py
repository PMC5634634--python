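import math

import networkx as nx
import numpy as np
import pytest

from csdnet import (degree_assortativity, degree_preserving_rewire,
                    edge_overlap_randomization, hypergeometric_enrichment,
                    intermediary_ranking, max_kcore, mean_clustering,
                    mean_shortest_path_comparison, null_model_comparison)
from conftest import typed_frame
from csdnet import assemble_network


def graph(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


def excess_degree_pearson(g):
    """Brute-force Newman assortativity: Pearson correlation of the
    degrees at the ends of every edge, both orientations."""
    xs, ys = [], []
    for a, b in g.edges():
        xs += [g.degree(a), g.degree(b)]
        ys += [g.degree(b), g.degree(a)]
    return np.corrcoef(xs, ys)[0, 1]


class TestAssortativity:
    def test_star_is_maximally_disassortative(self):
        g = graph([("X", f"L{i}") for i in range(4)])
        assert degree_assortativity(g) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        assert math.isnan(degree_assortativity(nx.cycle_graph(5)))

    def test_path_matches_brute_force(self):
        g = graph([("A", "B"), ("B", "C"), ("C", "D")])
        assert degree_assortativity(g) == \
            pytest.approx(excess_degree_pearson(g))


class TestKcoreAndClustering:
    def test_complete_graph_kcore(self):
        assert max_kcore(nx.complete_graph(4)) == 3

    def test_tree_kcore(self):
        assert max_kcore(nx.random_labeled_tree(10, seed=1)) == 1

    def test_k4_with_pendant(self):
        g = nx.complete_graph(4)
        g.add_edge(0, "pendant")
        assert max_kcore(g) == 3

    def test_triangle_clustering(self):
        assert mean_clustering(nx.complete_graph(3)) == 1.0

    def test_star_clustering(self):
        assert mean_clustering(nx.star_graph(4)) == 0.0

    def test_triangle_with_pendant(self):
        # per-node coefficients (1/3, 1, 1, 0) average to 7/12
        g = nx.complete_graph(3)
        g.add_edge(0, 3)
        assert mean_clustering(g) == pytest.approx(7 / 12)


class TestRewire:
    def test_degree_multiset_preserved(self):
        g = nx.gnm_random_graph(30, 60, seed=4)
        r = degree_preserving_rewire(g, swaps_per_edge=10, seed=0)
        assert sorted(d for _, d in r.degree()) == \
            sorted(d for _, d in g.degree())
        assert not any(a == b for a, b in r.edges())

    def test_triangle_unchanged(self):
        g = nx.complete_graph(3)
        r = degree_preserving_rewire(g, seed=1)
        assert set(map(frozenset, r.edges())) == \
            set(map(frozenset, g.edges()))

    def test_two_disjoint_edges(self):
        g = graph([("A", "B"), ("C", "D")])
        r = degree_preserving_rewire(g, seed=2)
        assert r.number_of_edges() == 2
        assert all(d == 1 for _, d in r.degree())


class TestNullModelComparison:
    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(25, 50, seed=7)
        a = null_model_comparison(g, "clustering", n_random=10, seed=3)
        b = null_model_comparison(g, "clustering", n_random=10, seed=3)
        assert a == b

    def test_rigid_degree_sequence_flagged_degenerate(self):
        cmp = null_model_comparison(nx.star_graph(5), "max_kcore",
                                    n_random=5, seed=0)
        assert cmp.degenerate and math.isnan(cmp.z)

    def test_per_type_variant(self, mixed_network):
        cmp = null_model_comparison(mixed_network, "clustering",
                                    n_random=5, seed=0, link_type="C")
        assert cmp.empirical == 0.0


class TestEdgeOverlap:
    def test_self_overlap_is_edge_count(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D")]
        obs, _, _ = edge_overlap_randomization(
            edges, edges, "ABCDEF", n_random=20, seed=0)
        assert obs == 3

    def test_disjoint_reference(self):
        obs, _, p = edge_overlap_randomization(
            [("A", "B")], [("X", "Y")], ["A", "B"], n_random=50, seed=0)
        assert obs == 0
        assert p == 1.0

    def test_saturated_pool_null_mean_equals_edges(self):
        pool = list("ABCDEF")
        reference = [(a, b) for i, a in enumerate(pool)
                     for b in pool[i + 1:]]  # all 15 pairs
        edges = [("A", "B"), ("C", "D"), ("E", "F")]
        obs, null_mean, _ = edge_overlap_randomization(
            edges, reference, pool, n_random=30, seed=1)
        assert obs == 3
        assert null_mean == 3.0  # every sampled pair is in the reference


class TestShortestPaths:
    PATH = graph([("A", "B"), ("B", "C"), ("C", "D")])

    def test_direct_edges_mean_one(self):
        mean, *_ = mean_shortest_path_comparison(
            [("A", "B"), ("B", "C")], self.PATH, n_samples=20, seed=0)
        assert mean == 1.0

    def test_derived_mean(self):
        mean, *_ = mean_shortest_path_comparison(
            [("A", "C"), ("A", "D")], self.PATH, n_samples=20, seed=0)
        assert mean == pytest.approx(2.5)

    def test_disconnected_pair_dropped(self):
        ref = graph([("A", "B"), ("X", "Y")])
        mean, *_ = mean_shortest_path_comparison(
            [("A", "B"), ("A", "X")], ref, n_samples=10, seed=0)
        assert mean == 1.0  # only (A,B) usable

    def test_no_usable_pair(self):
        with pytest.raises(ValueError):
            mean_shortest_path_comparison([("Q", "R")], self.PATH,
                                          n_samples=5, seed=0)


class TestIntermediaryRanking:
    def test_single_mediator(self):
        ref = graph([("A", "X"), ("X", "B")])
        assert intermediary_ranking([("A", "B")], ref) == [("X", 1)]

    def test_direct_pair_contributes_nothing(self):
        ref = graph([("A", "B")])
        assert intermediary_ranking([("A", "B")], ref) == []

    def test_parallel_shortest_paths_both_counted(self):
        ref = graph([("A", "X"), ("X", "B"), ("A", "Y"), ("Y", "B")])
        assert dict(intermediary_ranking([("A", "B")], ref)) == \
            {"X": 1, "Y": 1}

    def test_long_paths_excluded(self):
        ref = graph([("A", "P"), ("P", "Q"), ("Q", "R"), ("R", "B")])
        assert intermediary_ranking([("A", "B")], ref, max_steps=3) == []


class TestEnrichment:
    def test_derived_hypergeometric_value(self):
        background = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3"}
        res = hypergeometric_enrichment(query, background,
                                        {"set1": gene_set})
        assert res[0].p_raw == pytest.approx(5 / 210)
        assert res[0].p_corrected == pytest.approx(5 / 210)
        assert res[0].fold == pytest.approx(4 / (4 * 5 / 10))

    def test_query_equals_background(self):
        bg = {"a", "b", "c", "d"}
        res = hypergeometric_enrichment(bg, bg, {"s": {"a", "b"}})
        assert res[0].p_raw == pytest.approx(1.0)

    def test_zero_overlap(self):
        bg = {"a", "b", "c", "d"}
        res = hypergeometric_enrichment({"a"}, bg, {"s": {"c", "d"}})
        assert res[0].p_raw == pytest.approx(1.0)

    def test_bonferroni_scales_with_set_count(self):
        bg = {f"g{i}" for i in range(10)}
        sets = {f"s{j}": {f"g{i}" for i in range(5)} for j in range(4)}
        res = hypergeometric_enrichment({"g0", "g1", "g2", "g3"}, bg, sets)
        assert res[0].p_corrected == pytest.approx(min(1, 4 * res[0].p_raw))


def test_d_subnetwork_of_star_has_zero_clustering(mixed_network):
    sub = mixed_network.subnetwork("D")
    assert mean_clustering(sub) == 0.0
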