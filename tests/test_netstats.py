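import numpy as np
import pytest

from edgetics.netstats import (compare_centrality, disrupted_subnetworks,
                               edge_betweenness, flow_betweenness,
                               global_efficiency)

from _oracles import (brute_current_flow_betweenness, brute_edge_betweenness,
                      brute_global_efficiency, brute_pair_distances,
                      random_connected_graph)
from conftest import make_interactome


def from_edges(edges):
    return make_interactome([(f"n{a}", f"n{b}") for a, b in edges])


class TestEdgeBetweenness:
    def test_single_edge(self):
        g = make_interactome([("a", "b")])
        assert edge_betweenness(g) == {("a", "b"): 1.0}

    def test_path_middle_edges_carry_two_pairs(self, path3):
        eb = edge_betweenness(path3)
        assert eb[("a", "b")] == pytest.approx(2.0)
        assert eb[("b", "c")] == pytest.approx(2.0)

    def test_triangle_unit_scores(self, triangle):
        assert all(v == pytest.approx(1.0)
                   for v in edge_betweenness(triangle).values())

    def test_self_loops_dropped(self):
        g = make_interactome([("a", "b")], self_loops=["a"])
        assert edge_betweenness(g) == {("a", "b"): 1.0}

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            nodes, edges = random_connected_graph(rng, n)
            eb = edge_betweenness(from_edges(edges))
            oracle = brute_edge_betweenness(nodes, edges)
            for (a, b), v in oracle.items():
                assert eb[(f"n{a}", f"n{b}")] == pytest.approx(v)

    def test_total_betweenness_equals_total_pair_distance(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            nodes, edges = random_connected_graph(rng, int(rng.integers(4, 12)))
            eb = edge_betweenness(from_edges(edges))
            dists = brute_pair_distances(nodes, edges)
            assert sum(eb.values()) == pytest.approx(
                sum(v for v in dists.values() if np.isfinite(v)))


class TestFlowBetweenness:
    def test_tree_flow_equals_shortest_path_betweenness(self):
        g = make_interactome([("a", "b"), ("b", "c"), ("b", "d"), ("d", "e")])
        eb, fb = edge_betweenness(g), flow_betweenness(g)
        for e, v in eb.items():
            assert fb[e] == pytest.approx(v)

    def test_path_kirchhoff_solution(self, path3):
        assert flow_betweenness(path3)[("a", "b")] == pytest.approx(2.0)

    def test_triangle_symmetric_by_automorphism(self, triangle):
        vals = list(flow_betweenness(triangle).values())
        assert max(vals) == pytest.approx(min(vals))

    def test_matches_laplacian_pseudoinverse_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            nodes, edges = random_connected_graph(rng, int(rng.integers(3, 9)))
            fb = flow_betweenness(from_edges(edges))
            oracle = brute_current_flow_betweenness(nodes, edges)
            for (a, b), v in oracle.items():
                assert fb[(f"n{a}", f"n{b}")] == pytest.approx(v, abs=1e-9)

    def test_disconnected_graph_computed_per_component(self):
        g = make_interactome([("a", "b"), ("c", "d"), ("d", "e")])
        fb = flow_betweenness(g)
        assert fb[("a", "b")] == pytest.approx(1.0)
        assert fb[("c", "d")] == pytest.approx(2.0)


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        g = from_edges([(i, j) for i in range(5) for j in range(i + 1, 5)])
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_path3_closed_form(self, path3):
        assert global_efficiency(path3) == pytest.approx(5 / 6)

    def test_isolated_pair_of_nodes_zero(self):
        from edgetics.io import Interactome
        g = Interactome()
        g.add_node("a")
        g.add_node("b")
        assert global_efficiency(g) == 0.0

    def test_single_node_rejected(self):
        from edgetics.io import Interactome
        g = Interactome()
        g.add_node("a")
        with pytest.raises(ValueError):
            global_efficiency(g)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            n = int(rng.integers(4, 10))
            nodes, edges = random_connected_graph(rng, n, p=0.3)
            g = from_edges(edges)
            before = global_efficiency(g)
            assert 0.0 <= before <= 1.0
            missing = [(i, j) for i in range(n) for j in range(i + 1, n)
                       if (i, j) not in set(edges)]
            if missing:
                extra = missing[int(rng.integers(len(missing)))]
                g.add_edge(f"n{extra[0]}", f"n{extra[1]}")
                assert global_efficiency(g) >= before - 1e-12

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        nodes, edges = random_connected_graph(rng, 7)
        assert global_efficiency(from_edges(edges)) == pytest.approx(
            brute_global_efficiency(nodes, edges))


class TestDisruptedSubnetworks:
    def test_shared_edges_excluded_from_both(self, triangle):
        subs = disrupted_subnetworks(
            triangle,
            {"pathogenic": [("a", "b"), ("b", "c")],
             "population": [("b", "c"), ("a", "c")]},
            shared_edge_policy="exclude")
        sub_a, sub_b, report = subs
        assert sub_a.edges == {("a", "b")}
        assert sub_b.edges == {("a", "c")}
        assert report["n_shared_edges"] == 1

    def test_identical_sets_empty_after_exclusion(self, triangle):
        e = [("a", "b"), ("b", "c")]
        sub_a, sub_b, _ = disrupted_subnetworks(
            triangle, {"x": e, "y": e}, "exclude")
        assert sub_a.edges == set() and sub_b.edges == set()

    def test_disjoint_sets_unchanged(self, triangle):
        sub_a, sub_b, report = disrupted_subnetworks(
            triangle, {"x": [("a", "b")], "y": [("b", "c")]}, "exclude")
        assert sub_a.edges == {("a", "b")} and sub_b.edges == {("b", "c")}
        assert report["n_shared_edges"] == 0


class TestCompareCentrality:
    def test_identical_edge_sets_show_no_difference(self, triangle):
        rep = compare_centrality(triangle, [("a", "b")], [("a", "b")])
        assert rep["betweenness"]["p"] == pytest.approx(1.0)

    def test_empty_edge_set_rejected(self, triangle):
        with pytest.raises(ValueError):
            compare_centrality(triangle, [], [("a", "b")])

    def test_planted_top_decile_shift_detected_at_50_edges_per_set(self):
        # one arm restricted to top-decile betweenness edges, the other a
        # uniform sample of the remainder; 50 edges per arm
        import networkx as nx
        G = nx.gnp_random_graph(120, 0.05, seed=31)
        G = G.subgraph(max(nx.connected_components(G), key=len))
        g = make_interactome([(f"n{a}", f"n{b}") for a, b in G.edges])
        eb = edge_betweenness(g)
        ranked = sorted(eb, key=eb.get)
        top_decile = ranked[-max(50, len(ranked) // 10):]
        rng = np.random.default_rng(23)
        rest = ranked[: len(ranked) - len(top_decile)]
        high = [top_decile[i] for i in rng.choice(len(top_decile), 50,
                                                  replace=False)]
        low = [rest[i] for i in rng.choice(len(rest), 50, replace=False)]
        rep = compare_centrality(g, high, low)
        assert rep["betweenness"]["p"] < 0.05
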