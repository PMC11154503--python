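"""Population edgetic profiles and their cross-population divergence.

For a protein enriched with interaction-disrupting mutations, the edgetic
profile of a population is a binary vector over the protein's detrimental
(interaction, variant) positions: 1 where the variant segregates in that
population (allele frequency strictly > 0), 0 where it is absent.  All
populations share one position space per protein, ordered by canonical
interaction key and then variant id, so profiles are directly comparable.

Divergence between two populations is the Manhattan distance between
their bit vectors, normalized by the number of positions l; the
per-protein summary is the sum of normalized distances over unordered
population pairs divided by N(N−1) ("ordered" convention; the unordered
N(N−1)/2 denominator is available).  Significance is assessed by
independently shuffling every population's bit vector (preserving its
popcount, i.e. the population's mutation burden) and recomputing the
statistic R times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .effects import DETRIMENTAL, EdgeticAnnotation
from .io import DEFAULT_POPULATIONS, EdgeKey, MutationRecord, check_populations


@dataclass(frozen=True)
class ProfilePositionSpace:
    """Ordered (interaction, variant) positions of one protein's profile."""

    protein: str
    positions: tuple[tuple[EdgeKey, str], ...]

    @property
    def l(self) -> int:  # noqa: E743 - field name from the distance formula
        return len(self.positions)

    @property
    def interactions(self) -> tuple[EdgeKey, ...]:
        seen: list[EdgeKey] = []
        for e, _ in self.positions:
            if not seen or seen[-1] != e:
                seen.append(e)
        return tuple(seen)

    @property
    def m(self) -> int:
        return len(self.interactions)


@dataclass(frozen=True)
class EdgeticProfile:
    protein: str
    population: str
    space: ProfilePositionSpace
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != self.space.l:
            raise ValueError("bit vector length does not match position space")


def position_space(
    annotations: Iterable[EdgeticAnnotation], protein: str
) -> ProfilePositionSpace:
    """Detrimental (interaction, variant) positions of ``protein``, ordered."""
    pos = sorted(
        {
            (a.interaction, a.variant_id)
            for a in annotations
            if a.protein == protein and a.effect == DETRIMENTAL
        }
    )
    if not pos:
        raise ValueError(f"protein {protein} has no detrimental annotations")
    return ProfilePositionSpace(protein, tuple(pos))


def build_profiles(
    annotations: Iterable[EdgeticAnnotation],
    mutations: Sequence[MutationRecord],
    protein: str,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
) -> dict[str, EdgeticProfile]:
    """One profile per population over the protein's shared position space.

    Neutral and beneficial (interaction-preserving) annotations are
    excluded; presence means allele frequency strictly greater than zero.
    """
    pops = check_populations(populations)
    space = position_space(annotations, protein)
    by_variant = {m.variant_id: m for m in mutations}
    missing = sorted({v for _, v in space.positions} - set(by_variant))
    if missing:
        raise ValueError(f"variants missing from mutation table: {missing[:10]}")
    out = {}
    for pop in pops:
        bits = tuple(
            int(by_variant[v].present_in(pop)) for _, v in space.positions
        )
        out[pop] = EdgeticProfile(protein, pop, space, bits)
    return out


def profile_distance(x: EdgeticProfile, y: EdgeticProfile) -> tuple[int, float]:
    """Manhattan distance between two profiles and its l-normalized form."""
    if x.space != y.space:
        raise ValueError("profiles live in different position spaces")
    d = sum(abs(a - b) for a, b in zip(x.bits, y.bits))
    return d, d / x.space.l


def _distance_sum(bits: np.ndarray) -> float:
    """Sum of normalized Manhattan distances over unordered row pairs."""
    n, l = bits.shape
    diff = np.abs(bits[:, None, :].astype(np.int16) - bits[None, :, :]).sum(axis=2)
    return float(diff.sum()) / 2.0 / l


def average_population_distance(
    profiles: Mapping[str, EdgeticProfile],
    pair_normalization: str = "ordered",
) -> float:
    """Average normalized profile distance across population pairs.

    With ``pair_normalization='ordered'`` the unordered-pair sum is divided
    by N(N−1); with ``'unordered'`` by N(N−1)/2 (a true pairwise mean).
    """
    pops = sorted(profiles)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    bits = np.array([profiles[p].bits for p in pops], dtype=np.int16)
    return _normalized_average(_distance_sum(bits), len(pops), pair_normalization)


def _normalized_average(unordered_sum: float, n: int, pair_normalization: str) -> float:
    if pair_normalization == "ordered":
        return unordered_sum / (n * (n - 1))
    if pair_normalization == "unordered":
        return unordered_sum / (n * (n - 1) / 2)
    raise ValueError(f"unknown pair_normalization {pair_normalization!r}")


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd == 0)
    p_empirical: float
    R: int
    seed: int
    pair_normalization: str
    null_values: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if np.isnan(self.z) else self.z,
            "p_empirical": self.p_empirical,
            "R": self.R,
            "seed": self.seed,
            "pair_normalization": self.pair_normalization,
        }


def _stack(profiles: Mapping[str, EdgeticProfile]) -> np.ndarray:
    return np.array([profiles[p].bits for p in sorted(profiles)], dtype=np.int16)


def permutation_test(
    profiles_by_protein: Mapping[str, Mapping[str, EdgeticProfile]],
    R: int = 1000,
    seed: int = 0,
    pair_normalization: str = "ordered",
) -> PermutationResult:
    """Shuffle-based significance test for cross-population divergence.

    The observed statistic is the unweighted mean over proteins of the
    average pairwise population distance.  Each of the R null replicates
    independently permutes every population's bit vector within its
    protein's position space (preserving per-population burden) and
    recomputes the statistic.  The empirical p-value is the one-sided
    upper tail (1 + #{null ≥ observed}) / (1 + R).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not profiles_by_protein:
        raise ValueError("no proteins supplied")
    mats = {prot: _stack(profs) for prot, profs in profiles_by_protein.items()}
    n_pops = {m.shape[0] for m in mats.values()}
    if len(n_pops) != 1:
        raise ValueError("inconsistent population sets across proteins")
    n = n_pops.pop()
    if n < 2:
        raise ValueError("need at least two populations")

    def statistic(arrays: Mapping[str, np.ndarray]) -> float:
        vals = [
            _normalized_average(_distance_sum(b), n, pair_normalization)
            for b in arrays.values()
        ]
        return float(np.mean(vals))

    observed = statistic(mats)
    rng = np.random.default_rng(seed)
    null = np.empty(R)
    for r in range(R):
        shuffled = {prot: rng.permuted(b, axis=1) for prot, b in mats.items()}
        null[r] = statistic(shuffled)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if R > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p = (1 + int((null >= observed).sum())) / (1 + R)
    return PermutationResult(
        observed, null_mean, null_sd, z, p, R, seed, pair_normalization, null
    )


def write_profiles(
    profiles_by_protein: Mapping[str, Mapping[str, EdgeticProfile]], path
) -> None:
    """Profiles TSV: protein, population, bits (0/1 string), l, m."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tpopulation\tbits\tl\tm\n")
        for prot in sorted(profiles_by_protein):
            for pop in sorted(profiles_by_protein[prot]):
                pr = profiles_by_protein[prot][pop]
                bits = "".join(map(str, pr.bits))
                fh.write(f"{prot}\t{pop}\t{bits}\t{pr.space.l}\t{pr.space.m}\n")
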