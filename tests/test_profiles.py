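import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgetics.io import MutationRecord
from edgetics.profiles import (EdgeticProfile, ProfilePositionSpace,
                               average_population_distance, build_profiles,
                               permutation_test, profile_distance)

POPS = ("AFR", "AMR", "EAS", "EUR", "SAS")


def profile(bits, space=None, pop="AFR"):
    space = space or ProfilePositionSpace(
        "P", tuple((("P", f"Q{i}"), f"v{i}") for i in range(len(bits))))
    return EdgeticProfile("P", pop, space, tuple(bits))


class TestBuildProfiles:
    def test_worked_twelve_position_profile(self, worked_profile_inputs):
        annotations, mutations = worked_profile_inputs
        profs = build_profiles(annotations, mutations, "P0", POPS)
        assert profs["EAS"].bits == (1, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1)
        assert profs["EAS"].space.m == 3 and profs["EAS"].space.l == 12

    def test_absent_population_is_all_zero(self, worked_profile_inputs):
        annotations, mutations = worked_profile_inputs
        profs = build_profiles(annotations, mutations, "P0", POPS)
        assert profs["EUR"].bits == (0,) * 12

    def test_variant_hitting_two_interactions_occupies_two_positions(self):
        from conftest import detrimental
        anns = [detrimental("v1", "P0", "Q1", protein="P0"),
                detrimental("v1", "P0", "Q2", protein="P0")]
        muts = [MutationRecord("v1", "P0", "A1V",
                               {p: (0.1 if p == "EAS" else 0.0) for p in POPS})]
        profs = build_profiles(anns, muts, "P0", POPS)
        assert profs["EAS"].space.l == 2
        assert profs["EAS"].bits == (1, 1)

    def test_protein_without_detrimental_annotations_rejected(self):
        with pytest.raises(ValueError, match="no detrimental"):
            build_profiles([], [], "P0", POPS)


class TestProfileDistance:
    def test_identity(self, worked_profile_inputs):
        annotations, mutations = worked_profile_inputs
        p = build_profiles(annotations, mutations, "P0", POPS)["EAS"]
        assert profile_distance(p, p) == (0, 0.0)

    def test_complement_reaches_maximal_distance(self, worked_profile_inputs):
        annotations, mutations = worked_profile_inputs
        p = build_profiles(annotations, mutations, "P0", POPS)["EAS"]
        comp = EdgeticProfile("P0", "X", p.space,
                              tuple(1 - b for b in p.bits))
        assert profile_distance(p, comp) == (12, 1.0)

    def test_two_bit_disagreement(self):
        s = ProfilePositionSpace("P", ((("P", "Q"), "v1"), (("P", "Q"), "v2")))
        assert profile_distance(profile((1, 0), s), profile((0, 1), s)) == (2, 1.0)

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError, match="position spaces"):
            profile_distance(profile((1, 0)), profile((1, 0, 1)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 12), st.data())
    def test_metric_axioms(self, l, data):
        s = ProfilePositionSpace(
            "P", tuple((("P", f"Q{i}"), f"v{i}") for i in range(l)))
        bits = st.lists(st.integers(0, 1), min_size=l, max_size=l)
        x, y, z = (profile(tuple(data.draw(bits)), s) for _ in range(3))
        dxy = profile_distance(x, y)[1]
        dyx = profile_distance(y, x)[1]
        dxz = profile_distance(x, z)[1]
        dzy = profile_distance(z, y)[1]
        assert dxy == dyx
        assert dxy <= dxz + dzy + 1e-12
        assert (dxy == 0) == (x.bits == y.bits)

    def test_invariant_under_common_permutation(self):
        rng = np.random.default_rng(3)
        l = 10
        s1 = ProfilePositionSpace(
            "P", tuple((("P", f"Q{i}"), f"v{i}") for i in range(l)))
        a = rng.integers(0, 2, l)
        b = rng.integers(0, 2, l)
        perm = rng.permutation(l)
        d1 = profile_distance(profile(tuple(a), s1), profile(tuple(b), s1))
        d2 = profile_distance(profile(tuple(a[perm]), s1),
                              profile(tuple(b[perm]), s1))
        assert d1 == d2


class TestAveragePopulationDistance:
    def test_ordered_denominator_matches_printed_formula(self):
        # three populations, all pairwise normalized distances 0.6
        s = ProfilePositionSpace(
            "P", tuple((("P", "Q"), f"v{i}") for i in range(10)))
        profs = {
            "A": profile((1, 1, 1, 0, 0, 0, 0, 0, 0, 0), s, "A"),
            "B": profile((0, 0, 0, 1, 1, 1, 0, 0, 0, 0), s, "B"),
            "C": profile((0, 0, 0, 0, 0, 0, 1, 1, 1, 0), s, "C"),
        }
        # every pair differs at 6 of 10 positions -> d_norm 0.6
        assert average_population_distance(profs, "ordered") == pytest.approx(
            3 * 0.6 / 6)
        assert average_population_distance(profs, "unordered") == pytest.approx(0.6)

    def test_identical_profiles_give_zero_under_either_convention(self):
        s = ProfilePositionSpace("P", ((("P", "Q"), "v1"),))
        profs = {p: profile((1,), s, p) for p in ("A", "B", "C")}
        assert average_population_distance(profs, "ordered") == 0.0
        assert average_population_distance(profs, "unordered") == 0.0

    def test_two_population_unordered_mean_is_the_single_distance(self):
        s = ProfilePositionSpace(
            "P", tuple((("P", "Q"), f"v{i}") for i in range(10)))
        profs = {"A": profile((1,) * 3 + (0,) * 7, s, "A"),
                 "B": profile((0,) * 3 + (1,) * 3 + (0,) * 4, s, "B")}
        assert average_population_distance(profs, "unordered") == pytest.approx(0.6)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            average_population_distance({"A": profile((1,))})


class TestPermutationTest:
    def test_all_zero_profiles_are_degenerate_null(self):
        s = ProfilePositionSpace(
            "P", tuple((("P", "Q"), f"v{i}") for i in range(4)))
        profs = {"P": {p: profile((0, 0, 0, 0), s, p) for p in POPS}}
        res = permutation_test(profs, R=50, seed=0)
        assert res.observed == 0.0
        assert res.p_empirical == 1.0
        assert np.isnan(res.z)

    def test_shuffles_preserve_population_burden(self):
        rng = np.random.default_rng(0)
        l = 30
        s = ProfilePositionSpace(
            "P", tuple((("P", "Q"), f"v{i}") for i in range(l)))
        profs = {"P": {p: profile(tuple(rng.integers(0, 2, l)), s, p)
                       for p in POPS}}
        res = permutation_test(profs, R=100, seed=1)
        # popcount-preserving shuffles bound the null away from impossible values
        counts = {p: sum(profs["P"][p].bits) for p in POPS}
        assert res.null_values.min() >= 0.0
        assert max(counts.values()) > 0  # sanity: non-degenerate input

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        l = 15
        s = ProfilePositionSpace(
            "P", tuple((("P", "Q"), f"v{i}") for i in range(l)))
        profs = {"P": {p: profile(tuple(rng.integers(0, 2, l)), s, p)
                       for p in POPS}}
        r1 = permutation_test(profs, R=50, seed=7)
        r2 = permutation_test(profs, R=50, seed=7)
        assert r1.p_empirical == r2.p_empirical
        assert np.array_equal(r1.null_values, r2.null_values)
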