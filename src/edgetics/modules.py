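"""Module detection: diffusion state distance clustering and DIAMOnD.

Two complementary detectors are provided.

Topology-only: the diffusion state distance (DSD) between two nodes is
the L1 distance between their k-step expected-visit vectors under a
simple symmetric random walk (start visit at t = 0 counted).  Unlike
shortest-path distance, DSD downweighs paths through hubs, which makes it
a sharper functional-similarity measure on protein networks.  Spectral
clustering of a Gaussian affinity built from the DSD matrix yields
candidate phenotype-associated modules, filtered to a size range.

Seed-based: DIAMOnD grows a disease module from known seed proteins by
repeatedly absorbing the outside node whose number of links into the
current module is most significant under a hypergeometric model of its
neighbor choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.cluster import SpectralClustering

from .io import Interactome


@dataclass
class DSDMatrix:
    """Pairwise diffusion state distances over a fixed node order."""

    nodes: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal; inf across components
    k: int

    def distance(self, a: str, b: str) -> float:
        ia, ib = self.nodes.index(a), self.nodes.index(b)
        return float(self.values[ia, ib])


@dataclass
class Module:
    members: frozenset[str]
    origin: str  # "topology" | "seeded"
    cluster_id: int | None = None
    trace: list[dict] = field(default_factory=list)  # DIAMOnD addition order

    @property
    def size(self) -> int:
        return len(self.members)


def _component_visit_matrix(sub: nx.Graph, k: int) -> tuple[list[str], np.ndarray]:
    nodes = sorted(sub.nodes)
    a = nx.to_numpy_array(sub, nodelist=nodes)
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        isolated = [n for n, d in zip(nodes, deg) if d == 0]
        raise ValueError(f"isolated nodes have no random walk: {isolated[:5]}")
    p = a / deg[:, None]
    visits = np.eye(len(nodes))  # t = 0: the start visit is counted
    step = np.eye(len(nodes))
    for _ in range(k):
        step = step @ p
        visits += step
    return nodes, visits


def dsd_vectors(g: Interactome, k: int) -> dict[str, np.ndarray]:
    """Expected k-step visit vectors D_k(A), per connected component.

    Each vector spans the whole node order (sorted); entries for nodes
    outside A's component are zero.  Row sums equal k + 1 exactly (one
    visit per time step, including the start).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    G = g.to_networkx(include_self_loops=False)
    all_nodes = sorted(G.nodes)
    index = {n: i for i, n in enumerate(all_nodes)}
    out: dict[str, np.ndarray] = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if sub.number_of_nodes() == 1:
            raise ValueError(f"isolated nodes have no random walk: {sorted(comp)}")
        nodes, visits = _component_visit_matrix(sub, k)
        for i, n in enumerate(nodes):
            vec = np.zeros(len(all_nodes))
            vec[[index[m] for m in nodes]] = visits[i]
            out[n] = vec
    return out


def dsd_matrix(g: Interactome, k: int = 5) -> DSDMatrix:
    """DSD(A, B) = ||D_k(A) − D_k(B)||_1; ∞ across components."""
    G = g.to_networkx(include_self_loops=False)
    all_nodes = tuple(sorted(G.nodes))
    index = {n: i for i, n in enumerate(all_nodes)}
    n = len(all_nodes)
    values = np.full((n, n), np.inf)
    np.fill_diagonal(values, 0.0)
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if sub.number_of_nodes() == 1:
            raise ValueError(f"isolated nodes have no random walk: {sorted(comp)}")
        nodes, visits = _component_visit_matrix(sub, k)
        idx = np.array([index[m] for m in nodes])
        d = np.abs(visits[:, None, :] - visits[None, :, :]).sum(axis=2)
        values[np.ix_(idx, idx)] = d
    return DSDMatrix(all_nodes, values, k)


def spectral_modules(
    dsd: DSDMatrix,
    n_clusters: int,
    size_range: tuple[int, int] = (3, 100),
    seed: int = 0,
) -> list[Module]:
    """Cluster the DSD matrix spectrally and keep size-conformant modules.

    Affinity exp(−DSD²/(2σ²)) with σ the median finite off-diagonal DSD;
    infinite (cross-component) distances map to zero affinity.  Clusters
    outside ``size_range`` are discarded.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    d = dsd.values
    off = d[np.triu_indices_from(d, k=1)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise ValueError("degenerate DSD matrix: no finite off-diagonal distances")
    sigma = float(np.median(finite))
    if sigma == 0:
        raise ValueError("degenerate DSD matrix: median off-diagonal distance is 0")
    with np.errstate(over="ignore"):
        affinity = np.exp(-(d**2) / (2 * sigma**2))
    affinity[~np.isfinite(d)] = 0.0
    if np.allclose(affinity, affinity.flat[0]):
        raise ValueError("degenerate affinity matrix (all entries equal)")
    labels = SpectralClustering(
        n_clusters=n_clusters, affinity="precomputed", random_state=seed,
        assign_labels="kmeans",
    ).fit_predict(affinity)
    lo, hi = size_range
    out = []
    for cid in sorted(set(labels)):
        members = frozenset(n for n, l in zip(dsd.nodes, labels) if l == cid)
        if lo <= len(members) <= hi:
            out.append(Module(members, "topology", cluster_id=int(cid)))
    return out


def n_clusters_for_target_size(n_nodes: int, target_size: int) -> int:
    """Helper: cluster count aiming at a desired mean module size."""
    return max(2, round(n_nodes / target_size))


def diamond_pvalue(N: int, s0: int, k: int, ks: int) -> float:
    """Hypergeometric connection significance of a candidate node.

    Probability that a node of degree ``k``, choosing its neighbors
    uniformly among the other ``N − 1`` nodes of which ``s0`` are module
    members, has at least ``ks`` links into the module.
    """
    if not (0 <= ks <= min(k, s0)):
        raise ValueError(f"need 0 <= ks <= min(k, s0); got ks={ks}, k={k}, s0={s0}")
    if not (1 <= k <= N - 1):
        raise ValueError(f"need 1 <= k <= N-1; got k={k}, N={N}")
    if not (0 <= s0 <= N - 1):
        raise ValueError(f"need 0 <= s0 <= N-1; got s0={s0}, N={N}")
    return float(stats.hypergeom.sf(ks - 1, N - 1, s0, k))


def diamond_expand(
    g: Interactome, seeds: Iterable[str], max_added: int = 100
) -> Module:
    """Grow a seeded disease module by iterative most-significant addition.

    At each step every outside node with at least one link into the
    current member set is scored with :func:`diamond_pvalue` (seeds count
    as members); the lowest p-value wins, ties broken by higher ks, then
    lower degree, then lexicographic id.  Stops after ``max_added``
    additions or when no connected candidate remains.
    """
    if max_added < 1:
        raise ValueError("max_added must be >= 1")
    G = g.to_networkx(include_self_loops=False)
    seeds = set(seeds)
    stray = seeds - set(G.nodes)
    if stray:
        raise ValueError(f"seeds not in interactome: {sorted(stray)[:5]}")
    N = G.number_of_nodes()
    members = set(seeds)
    trace: list[dict] = []
    for rank in range(1, max_added + 1):
        best = None
        for cand in sorted(set(G.nodes) - members):
            k = G.degree(cand)
            if k == 0:
                continue
            ks = sum(1 for nb in G.neighbors(cand) if nb in members)
            if ks == 0:
                continue
            p = diamond_pvalue(N, len(members), k, ks)
            key = (p, -ks, k, cand)
            if best is None or key < best[0]:
                best = (key, cand, k, ks, p)
        if best is None:
            warnings.warn(
                f"DIAMOnD stopped early at rank {rank}: no candidate with a "
                "link into the module", stacklevel=2)
            break
        _, cand, k, ks, p = best
        members.add(cand)
        trace.append({"rank": rank, "protein": cand, "ks": ks,
                      "degree": k, "p_value": p})
    return Module(frozenset(members), "seeded", trace=trace)


def write_modules(modules: Sequence[Module], path) -> None:
    """Module TSV: module_id, origin, members (comma-joined), size."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("module_id\torigin\tmembers\tsize\n")
        for i, m in enumerate(modules):
            fh.write(f"M{i:04d}\t{m.origin}\t{','.join(sorted(m.members))}\t{m.size}\n")


def write_diamond_trace(module: Module, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tprotein\tks\tdegree\tp_value\n")
        for row in module.trace:
            fh.write(f"{row['rank']}\t{row['protein']}\t{row['ks']}\t"
                     f"{row['degree']}\t{row['p_value']:.6g}\n")
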