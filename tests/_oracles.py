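"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths (and the library
algorithms) under test: shortest paths come from exhaustive simple-path
enumeration, current flows from a dense Laplacian pseudoinverse, and
hypergeometric tails from explicit combinatorial enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def all_simple_paths(adj: dict, s, t, _seen=None) -> list[list]:
    seen = _seen or {s}
    if s == t:
        return [[s]]
    out = []
    for nb in adj[s]:
        if nb not in seen:
            for rest in all_simple_paths(adj, nb, t, seen | {nb}):
                out.append([s] + rest)
    return out


def brute_edge_betweenness(nodes: list, edges: list[tuple]) -> dict:
    """Σ over unordered pairs of the fraction of shortest paths per edge."""
    adj: dict = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    score = {tuple(sorted(e)): 0.0 for e in edges}
    for u, v in itertools.combinations(nodes, 2):
        paths = all_simple_paths(adj, u, v)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for p in shortest:
            for a, b in zip(p, p[1:]):
                score[tuple(sorted((a, b)))] += 1.0 / len(shortest)
    return score


def brute_pair_distances(nodes: list, edges: list[tuple]) -> dict:
    """Shortest-path lengths over unordered pairs via path enumeration."""
    adj: dict = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for u, v in itertools.combinations(nodes, 2):
        paths = all_simple_paths(adj, u, v)
        out[(u, v)] = min((len(p) - 1 for p in paths), default=np.inf)
    return out


def brute_current_flow_betweenness(nodes: list, edges: list[tuple]) -> dict:
    """Sum over unordered pairs of |current| per edge, via pinv(Laplacian).

    Assumes a connected graph.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    L = np.zeros((n, n))
    for a, b in edges:
        i, j = idx[a], idx[b]
        L[i, j] -= 1
        L[j, i] -= 1
        L[i, i] += 1
        L[j, j] += 1
    Linv = np.linalg.pinv(L)
    score = {tuple(sorted(e)): 0.0 for e in edges}
    for s, t in itertools.combinations(nodes, 2):
        b = np.zeros(n)
        b[idx[s]], b[idx[t]] = 1.0, -1.0
        v = Linv @ b
        for a, c in edges:
            score[tuple(sorted((a, c)))] += abs(v[idx[a]] - v[idx[c]])
    return score


def brute_global_efficiency(nodes: list, edges: list[tuple]) -> float:
    d = brute_pair_distances(nodes, edges)
    n = len(nodes)
    total = sum(1.0 / v for v in d.values() if np.isfinite(v))
    return 2.0 * total / (n * (n - 1))


def brute_hypergeom_tail(N: int, s0: int, k: int, ks: int) -> float:
    """P(links into module >= ks) by enumerating neighbor choices."""
    total = comb(N - 1, k)
    fav = sum(
        comb(s0, j) * comb(N - 1 - s0, k - j)
        for j in range(ks, min(k, s0) + 1)
    )
    return fav / total


def brute_enrichment_pvalue(universe: set, term_genes: set, n_query: int,
                            k_obs: int) -> float:
    """P(overlap >= k_obs) by enumerating every query subset of the universe."""
    hits = 0
    total = 0
    for q in itertools.combinations(sorted(universe), n_query):
        total += 1
        if len(set(q) & term_genes) >= k_obs:
            hits += 1
    return hits / total


def random_connected_graph(rng: np.random.Generator, n: int,
                           p: float = 0.45) -> tuple[list, list[tuple]]:
    """A connected Erdős–Rényi-style graph built on a random spanning tree."""
    nodes = list(range(n))
    edges = set()
    order = rng.permutation(n)
    for i in range(1, n):
        a = int(order[rng.integers(i)])
        edges.add(tuple(sorted((a, int(order[i])))))
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < p:
            edges.add((u, v))
    return nodes, sorted(edges)
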