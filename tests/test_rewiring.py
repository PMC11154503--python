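import numpy as np
import pandas as pd
import pytest

from edgetics.effects import EdgeticAnnotation
from edgetics.io import MutationRecord
from edgetics.modules import Module
from edgetics.rewiring import (hierarchical_order, module_enrichment_test,
                               prevalence_matrix, random_module_null,
                               rewired_density)

from _oracles import random_connected_graph
from conftest import make_interactome

POPS = ("AFR", "AMR", "EAS", "EUR", "SAS")


def from_edges(edges):
    return make_interactome([(f"n{a}", f"n{b}") for a, b in edges])


class TestRewiredDensity:
    def test_direct_ratio(self):
        g = make_interactome([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d"),
                              ("d", "e")])
        mod = Module(frozenset("abcd"), "topology")
        d = rewired_density(g, mod, [("a", "b"), ("b", "c"), ("a", "d")])
        assert d.n_rewired_internal == 3
        assert d.density == pytest.approx(0.75)

    def test_no_disrupted_internal_edges(self):
        g = make_interactome([("a", "b")])
        mod = Module(frozenset("ab"), "topology")
        assert rewired_density(g, mod, []).density == 0.0

    def test_edge_leaving_the_module_not_counted(self):
        g = make_interactome([("a", "b"), ("b", "z")])
        mod = Module(frozenset("ab"), "topology")
        d = rewired_density(g, mod, [("b", "z")])
        assert d.n_rewired_internal == 0

    def test_member_self_interaction_counted(self):
        g = make_interactome([("a", "b")], self_loops=["a"])
        mod = Module(frozenset("ab"), "topology")
        d = rewired_density(g, mod, [("a", "a")])
        assert d.n_rewired_internal == 1

    def test_empty_module_rejected(self):
        g = make_interactome([("a", "b")])
        with pytest.raises(ValueError):
            rewired_density(g, Module(frozenset(), "topology"), [])


class TestRandomModuleNull:
    def test_size_multiset_preserved(self):
        rng = np.random.default_rng(1)
        _, edges = random_connected_graph(rng, 30, p=0.15)
        g = from_edges(edges)
        observed = [Module(frozenset(f"n{i}" for i in range(5)), "topology"),
                    Module(frozenset(f"n{i}" for i in range(8)), "topology")]
        null = random_module_null(g, observed, seed=3)
        assert sorted(m.size for m in null) == [5, 8]

    def test_same_seed_reproduces_the_null_set(self):
        rng = np.random.default_rng(2)
        _, edges = random_connected_graph(rng, 25, p=0.15)
        g = from_edges(edges)
        observed = [Module(frozenset(f"n{i}" for i in range(6)), "topology")]
        a = random_module_null(g, observed, seed=9)
        b = random_module_null(g, observed, seed=9)
        assert [m.members for m in a] == [m.members for m in b]

    def test_sampled_modules_are_connected(self):
        import networkx as nx
        rng = np.random.default_rng(3)
        _, edges = random_connected_graph(rng, 40, p=0.1)
        g = from_edges(edges)
        observed = [Module(frozenset(f"n{i}" for i in range(7)), "topology")
                    for _ in range(10)]
        G = g.to_networkx()
        for m in random_module_null(g, observed, seed=5):
            assert nx.is_connected(G.subgraph(m.members))

    def test_oversized_request_rejected(self):
        g = make_interactome([("a", "b")])
        observed = [Module(frozenset("abcde"), "topology")]
        with pytest.raises(ValueError, match="exceeds largest component"):
            random_module_null(g, observed, seed=0)


class TestModuleEnrichmentTest:
    def test_identical_samples_near_half(self):
        rng = np.random.default_rng(0)
        x = list(rng.random(30))
        rep = module_enrichment_test(x, list(x))
        assert 0.4 < rep["p"] < 0.6

    def test_calibrated_under_the_null(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            a, b = rng.random(30), rng.random(30)
            if module_enrichment_test(list(a), list(b))["p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            module_enrichment_test([], [0.1])


def _mut(vid, protein, pops_present):
    af = {p: (0.1 if p in pops_present else 0.0) for p in POPS}
    return MutationRecord(vid, protein, "A1V", af)


def _det(vid, a, b):
    return EdgeticAnnotation(vid, a, tuple(sorted((a, b))), 1.0, "detrimental")


class TestPrevalenceMatrix:
    def setup_method(self):
        self.g = make_interactome(
            [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d"), ("d", "e")])
        self.mod = {"M0": Module(frozenset("abcd"), "seeded")}

    def test_direct_per_population_ratios(self):
        anns = [_det("v1", "a", "b"), _det("v2", "b", "c"), _det("v3", "a", "d")]
        muts = [_mut("v1", "a", {"EAS"}), _mut("v2", "b", {"EAS", "AMR"}),
                _mut("v3", "a", set())]
        m = prevalence_matrix(self.g, self.mod, anns, muts, POPS)
        assert m.loc["M0", "EAS"] == pytest.approx(0.5)
        assert m.loc["M0", "AMR"] == pytest.approx(0.25)

    def test_absent_variant_contributes_nowhere(self):
        anns = [_det("v1", "a", "b")]
        muts = [_mut("v1", "a", set())]
        m = prevalence_matrix(self.g, self.mod, anns, muts, POPS)
        assert (m.loc["M0"] == 0).all()

    def test_fully_disrupted_everywhere_is_all_ones(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]
        anns = [_det(f"v{i}", a, b) for i, (a, b) in enumerate(edges)]
        muts = [_mut(f"v{i}", e[0], set(POPS)) for i, e in enumerate(edges)]
        m = prevalence_matrix(self.g, self.mod, anns, muts, POPS)
        assert (m.loc["M0"] == 1.0).all()

    def test_edge_free_module_yields_missing_cells(self):
        mods = {"M0": Module(frozenset(["a", "e"]), "seeded")}
        m = prevalence_matrix(self.g, mods, [], [], POPS)
        assert m.loc["M0"].isna().all()

    def test_monotone_when_a_population_gains_presence(self):
        anns = [_det("v1", "a", "b"), _det("v2", "b", "c")]
        before = prevalence_matrix(
            self.g, self.mod, anns,
            [_mut("v1", "a", {"EAS"}), _mut("v2", "b", set())], POPS)
        after = prevalence_matrix(
            self.g, self.mod, anns,
            [_mut("v1", "a", {"EAS"}), _mut("v2", "b", {"EAS"})], POPS)
        assert (after.loc["M0"] >= before.loc["M0"]).all()

    def test_shared_variants_make_identical_columns(self):
        anns = [_det("v1", "a", "b"), _det("v2", "c", "d")]
        muts = [_mut("v1", "a", set(POPS)), _mut("v2", "c", set(POPS))]
        m = prevalence_matrix(self.g, self.mod, anns, muts, POPS)
        assert (m.nunique(axis=1) == 1).all()


class TestHierarchicalOrder:
    def test_identical_rows_end_up_adjacent(self):
        m = pd.DataFrame(
            [[0.9, 0.8, 0.1], [0.1, 0.0, 0.9], [0.9, 0.8, 0.1]],
            index=["r1", "r2", "r3"], columns=["c1", "c2", "c3"])
        order = hierarchical_order(m)["row_order"]
        assert abs(order.index("r1") - order.index("r3")) == 1

    def test_row_permutation_invariance(self):
        m = pd.DataFrame(
            np.random.default_rng(4).random((5, 4)),
            index=[f"r{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(4)])
        shuffled = m.sample(frac=1, random_state=1)
        assert hierarchical_order(m) == hierarchical_order(shuffled)

    def test_block_structure_splits_at_the_root(self):
        hi = [[1.0, 1.0, 0.0], [0.9, 0.95, 0.05]]
        lo = [[0.0, 0.05, 1.0], [0.1, 0.0, 0.9]]
        m = pd.DataFrame(hi + lo, index=["h1", "h2", "l1", "l2"],
                         columns=["c1", "c2", "c3"])
        order = hierarchical_order(m)["row_order"]
        first_two = set(order[:2])
        assert first_two in ({"h1", "h2"}, {"l1", "l2"})

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_order(pd.DataFrame([[1.0, 2.0]], index=["r"],
                                            columns=["a", "b"]))
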