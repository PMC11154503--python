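"""Rewired-edge density of modules and population prevalence of rewiring.

A module's rewiring density is the number of module-internal interactions
hit by at least one detrimental mutation, normalized by the module's node
count.  Observed (phenotype-associated or disease) modules are compared
with a size-matched set of random connected modules via a one-sided
Mann-Whitney test.  Per-population rewiring prevalence of disease modules
is summarized as a module × population matrix suitable for heatmap
rendering, with hierarchically clustered row and column orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .effects import DETRIMENTAL, EdgeticAnnotation
from .io import (DEFAULT_POPULATIONS, EdgeKey, Interactome, MutationRecord,
                 check_populations, edge_key)
from .modules import Module


@dataclass
class RewiringDensity:
    module_id: str
    n_nodes: int
    n_edges_internal: int
    n_rewired_internal: int
    density: float  # rewired internal edges per module node


def internal_edges(g: Interactome, members: frozenset[str] | set[str]) -> set[EdgeKey]:
    """Parent edges with both endpoints in the module (self-loops included)."""
    return {e for e in g.edge_keys() if e[0] in members and e[1] in members}


def rewired_density(
    g: Interactome,
    module: Module,
    disrupted: Iterable[EdgeKey],
    module_id: str = "",
) -> RewiringDensity:
    if not module.members:
        raise ValueError("empty module")
    stray = module.members - g.nodes
    if stray:
        raise ValueError(f"module members not in interactome: {sorted(stray)[:5]}")
    internal = internal_edges(g, module.members)
    disrupted_set = {edge_key(*e) for e in disrupted}
    hit = internal & disrupted_set
    return RewiringDensity(
        module_id, len(module.members), len(internal), len(hit),
        len(hit) / len(module.members),
    )


def sample_connected_module(G: nx.Graph, size: int, rng: np.random.Generator) -> frozenset[str]:
    """Random connected node set grown by seeded neighborhood expansion."""
    nodes = sorted(G.nodes)
    for _ in range(1000):
        start = nodes[rng.integers(len(nodes))]
        members = {start}
        frontier = set(G.neighbors(start)) - members
        while len(members) < size and frontier:
            pick = sorted(frontier)[rng.integers(len(frontier))]
            members.add(pick)
            frontier |= set(G.neighbors(pick))
            frontier -= members
        if len(members) == size:
            return frozenset(members)
    raise ValueError(f"could not sample a connected module of size {size}")


def random_module_null(
    g: Interactome,
    observed: Sequence[Module],
    seed: int = 0,
    connected: bool = True,
) -> list[Module]:
    """Size-matched random modules (connected random-walk samples by default).

    With ``connected=False`` modules are uniform node samples instead,
    dropping the connectivity control.
    """
    if not observed:
        raise ValueError("observed module set is empty")
    G = g.to_networkx(include_self_loops=False)
    rng = np.random.default_rng(seed)
    largest = max((len(c) for c in nx.connected_components(G)), default=0)
    out: list[Module] = []
    nodes = sorted(G.nodes)
    for m in observed:
        if connected:
            if m.size > largest:
                raise ValueError(
                    f"module size {m.size} exceeds largest component ({largest})")
            members = sample_connected_module(G, m.size, rng)
        else:
            members = frozenset(rng.choice(nodes, size=m.size, replace=False))
        out.append(Module(members, "random"))
    return out


def density_table(
    g: Interactome,
    modules: Sequence[Module],
    disrupted: Iterable[EdgeKey],
    arm: str,
) -> pd.DataFrame:
    disrupted = {edge_key(*e) for e in disrupted}
    rows = []
    for i, m in enumerate(modules):
        d = rewired_density(g, m, disrupted, module_id=f"{arm}{i:04d}")
        rows.append({"module_id": d.module_id, "n_nodes": d.n_nodes,
                     "n_edges_internal": d.n_edges_internal,
                     "n_rewired": d.n_rewired_internal,
                     "density": d.density, "arm": arm})
    return pd.DataFrame(rows)


def module_enrichment_test(
    densities_observed: Sequence[float], densities_null: Sequence[float]
) -> dict:
    """One-sided Mann-Whitney U: observed densities greater than null."""
    if len(densities_observed) == 0 or len(densities_null) == 0:
        raise ValueError("both density samples must be non-empty")
    u, p = stats.mannwhitneyu(densities_observed, densities_null,
                              alternative="greater")
    return {
        "U": float(u), "p": float(p),
        "median_observed": float(np.median(densities_observed)),
        "median_null": float(np.median(densities_null)),
        "n_observed": len(densities_observed), "n_null": len(densities_null),
    }


def prevalence_matrix(
    g: Interactome,
    disease_modules: Mapping[str, Module],
    annotations: Iterable[EdgeticAnnotation],
    mutations: Sequence[MutationRecord],
    populations: Sequence[str] = DEFAULT_POPULATIONS,
    denominator: str = "edges",
) -> pd.DataFrame:
    """Module × population fraction of internal edges rewired per population.

    Cell (m, p) counts module-internal edges carrying at least one
    detrimental variant segregating (AF > 0) in population p, divided by
    the module's internal edge count (or node count with
    ``denominator='nodes'``).  Edge-free modules yield missing cells.
    """
    if denominator not in ("edges", "nodes"):
        raise ValueError(f"unknown denominator {denominator!r}")
    pops = check_populations(populations)
    by_variant = {m.variant_id: m for m in mutations}
    det_by_edge: dict[EdgeKey, set[str]] = {}
    for a in annotations:
        if a.effect == DETRIMENTAL:
            det_by_edge.setdefault(a.interaction, set()).add(a.variant_id)
    data = {}
    for mid, module in sorted(disease_modules.items()):
        internal = internal_edges(g, module.members)
        row = {}
        for pop in pops:
            hit = sum(
                1 for e in internal
                if any(by_variant[v].present_in(pop)
                       for v in det_by_edge.get(e, ()) if v in by_variant)
            )
            denom = len(internal) if denominator == "edges" else module.size
            row[pop] = hit / denom if denom else np.nan
        data[mid] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=list(pops))


def hierarchical_order(matrix: pd.DataFrame) -> dict:
    """Average-linkage Euclidean ordering of rows and columns.

    Missing cells are zero-imputed for ordering only.  Rows and columns
    are pre-sorted by label so the dendrogram (and hence the leaf order)
    is invariant to the input permutation.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("matrix must have at least 2 rows and 2 columns")
    m = matrix.sort_index(axis=0).sort_index(axis=1).fillna(0.0)

    def order(values: np.ndarray, labels: list[str]) -> tuple[list[str], list]:
        lk = linkage(pdist(values, metric="euclidean"), method="average")
        return [labels[i] for i in leaves_list(lk)], lk.tolist()

    row_order, row_linkage = order(m.to_numpy(), list(m.index))
    col_order, col_linkage = order(m.to_numpy().T, list(m.columns))
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_linkage,
        "col_linkage": col_linkage,
    }
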