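import pytest

from edgetics import synth
from edgetics.effects import EdgeticAnnotation
from edgetics.io import Interactome, MutationRecord


def make_interactome(edges, self_loops=()):
    g = Interactome()
    for a, b in edges:
        g.add_edge(a, b)
    for n in self_loops:
        g.add_edge(n, n)
    return g


@pytest.fixture
def path3():
    """The 3-node path a–b–c."""
    return make_interactome([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle():
    return make_interactome([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def default_scenario():
    return synth.generate(synth.ScenarioConfig(seed=11))


def detrimental(variant, a, b, protein=None):
    return EdgeticAnnotation(variant, protein or a, tuple(sorted((a, b))),
                             1.0, "detrimental")


@pytest.fixture
def worked_profile_inputs():
    """A protein with 12 detrimental positions over 3 interactions.

    The position space orders interactions by canonical key and variants
    by id, so positions 1..12 map to Q1:v01..v05, Q2:v06..v09,
    Q3:v10..v12.  Population EAS carries the variants at positions
    {1, 4, 6, 7, 8, 11, 12}.
    """
    partners = {"Q1": 5, "Q2": 4, "Q3": 3}
    annotations, mutations = [], []
    present_eas = {1, 4, 6, 7, 8, 11, 12}
    pos = 0
    for q, count in sorted(partners.items()):
        for _ in range(count):
            pos += 1
            vid = f"v{pos:02d}"
            annotations.append(detrimental(vid, "P0", q, protein="P0"))
            af = {p: 0.0 for p in ("AFR", "AMR", "EAS", "EUR", "SAS")}
            if pos in present_eas:
                af["EAS"] = 0.2
            af["AFR"] = 0.3  # AFR carries everything; a contrast population
            mutations.append(MutationRecord(vid, "P0", f"A{pos}V", af))
    return annotations, mutations
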