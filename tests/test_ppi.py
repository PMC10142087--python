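"""Interaction-network construction, topology statistics, and hub scores."""

import math

import networkx as nx
import numpy as np
import pytest

from netpharm.ppi import (HUB_METHODS, consensus_top, degree_score,
                          enumerate_maximal_cliques, load_interaction_table,
                          mcc_score, mnc_score, network_stats, rank_nodes)

from _bruteforce import (brute_degree, brute_maximal_cliques, brute_mcc,
                         brute_mnc, random_graph)


class TestLoadInteractionTable:
    def test_cutoff_inclusive_and_autoscaled(self):
        rows = [("A", "B", 350), ("A", "C", 400), ("B", "C", 900)]
        g = load_interaction_table(rows, min_confidence=0.400)
        assert g.number_of_edges() == 2
        assert not g.has_edge("A", "B")
        assert g["A"]["C"]["confidence"] == pytest.approx(0.400)

    def test_reversed_pairs_collapse_keeping_max(self):
        g = load_interaction_table([("A", "B", 0.5), ("B", "A", 0.9)], 0.4)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["confidence"] == 0.9

    def test_self_loops_dropped(self):
        g = load_interaction_table([("A", "A", 0.9), ("A", "B", 0.9)], 0.4)
        assert g.number_of_edges() == 1

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            load_interaction_table([("A", "B", -5)], 0.4)

    def test_malformed_rows_rejected(self):
        with pytest.raises(ValueError):
            load_interaction_table([("A", "B")], 0.4)

    def test_include_nodes_adds_isolates(self):
        g = load_interaction_table([("A", "B", 0.9)], 0.4, include_nodes=["A", "B", "Z"])
        assert "Z" in g and g.degree("Z") == 0


class TestNetworkStats:
    def test_triangle(self, triangle):
        s = network_stats(triangle)
        assert (s.average_neighbors, s.diameter, s.radius) == (2.0, 1, 1)

    def test_path_graph(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        s = network_stats(g)
        assert s.average_neighbors == 1.333
        assert (s.diameter, s.radius) == (2, 1)

    def test_average_neighbors_is_2e_over_n(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            nodes, edges = random_graph(rng, int(rng.integers(3, 20)), 0.3)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            s = network_stats(g)
            assert s.average_neighbors == round(2 * len(edges) / len(nodes), 3)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_stats(nx.Graph())


class TestScores:
    def test_triangle_scores(self, triangle):
        # single maximal 3-clique: MCC = 2! = 2; both neighbors joined: MNC = 2
        assert mcc_score(triangle, "A") == 2
        assert mnc_score(triangle, "A") == 2
        assert degree_score(triangle, "A") == 2

    def test_k4_mcc(self):
        g = nx.complete_graph(4)
        assert mcc_score(g, 0) == math.factorial(3)

    def test_star_center(self, star5):
        # four 2-cliques each contribute 1!; neighbors mutually unconnected
        assert mcc_score(star5, "HUB") == 4
        assert mnc_score(star5, "HUB") == 1
        assert degree_score(star5, "HUB") == 4

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("X")
        assert mcc_score(g, "X") == 1   # singleton maximal clique, 0! = 1
        assert mnc_score(g, "X") == 0
        assert degree_score(g, "X") == 0

    def test_unknown_node_rejected(self, triangle):
        for fn in (mcc_score, mnc_score, degree_score):
            with pytest.raises(KeyError):
                fn(triangle, "ZZ")


class TestCliqueEnumeration:
    def test_k3_single_clique(self, triangle):
        assert enumerate_maximal_cliques(triangle) == [frozenset("ABC")]

    def test_path(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        found = set(enumerate_maximal_cliques(g))
        assert found == {frozenset("AB"), frozenset("BC")}

    def test_edgeless_graph_yields_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("ABCD")
        assert set(enumerate_maximal_cliques(g)) == {frozenset(c) for c in "ABCD"}

    def test_matches_bruteforce_and_relabeling_invariant(self):
        rng = np.random.default_rng(17)
        nodes, edges = random_graph(rng, 9, 0.4)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        assert set(enumerate_maximal_cliques(g)) == set(brute_maximal_cliques(nodes, edges))
        # relabeled graph yields the relabeled cliques
        mapping = {v: f"R-{v}" for v in nodes}
        g2 = nx.relabel_nodes(g, mapping)
        relabeled = {frozenset(mapping[v] for v in c) for c in enumerate_maximal_cliques(g)}
        assert set(enumerate_maximal_cliques(g2)) == relabeled


def test_scores_match_bruteforce_on_random_graphs():
    """MCC/MNC/Degree agree with the all-subsets / flood-fill oracles."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(3, 11))
        nodes, edges = random_graph(rng, n, float(rng.uniform(0.1, 0.7)))
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        exp_mcc, exp_mnc, exp_deg = (brute_mcc(nodes, edges),
                                     brute_mnc(nodes, edges),
                                     brute_degree(nodes, edges))
        for v in nodes:
            assert mcc_score(g, v) == exp_mcc[v]
            assert mnc_score(g, v) == exp_mnc[v]
            assert degree_score(g, v) == exp_deg[v]


class TestRanking:
    def test_complete_graph_ties_break_lexicographically(self):
        g = nx.Graph()
        nodes = ["D", "B", "A", "C"]
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                g.add_edge(a, b)
        r = rank_nodes(g, "Degree", 4)
        assert [e[0] for e in r.entries] == ["A", "B", "C", "D"]

    def test_star_top1_is_center(self, star5):
        for method in HUB_METHODS:
            assert rank_nodes(star5, method, 1).top(1) == ["HUB"]

    def test_k_exceeding_node_count_truncates_with_warning(self, triangle):
        with pytest.warns(UserWarning, match="exceeds node count"):
            r = rank_nodes(triangle, "Degree", 10)
        assert len(r.entries) == 3

    def test_scores_non_increasing(self, study):
        from netpharm.ppi import load_interaction_table
        net = load_interaction_table(study.ppi_edges, 0.4)
        for method in HUB_METHODS:
            scores = [s for _, s in rank_nodes(net, method, 42).entries]
            assert scores == sorted(scores, reverse=True)

    def test_unknown_method_rejected(self, triangle):
        with pytest.raises(ValueError):
            rank_nodes(triangle, "EPC", 1)


class TestConsensus:
    def test_identical_rankings(self, star5):
        rankings = [rank_nodes(star5, m, 3) for m in ("Degree", "Degree")]
        assert consensus_top(rankings, 3) == sorted(rankings[0].top(3))

    def test_disjoint_rankings_empty(self, triangle, star5):
        r1 = rank_nodes(triangle, "Degree", 3)
        r2 = rank_nodes(star5, "Degree", 3)
        assert consensus_top([r1, r2], 3) == []

    def test_empty_rankings_rejected(self):
        with pytest.raises(ValueError):
            consensus_top([], 3)
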