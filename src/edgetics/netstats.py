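"""Edge centralities, global efficiency, and disrupted-subnetwork comparison.

Interactions rewired by detrimental mutations are characterized by two
edge centralities on the full interactome — shortest-path edge betweenness
and current-flow (random-walk) betweenness — and collapsed into
subnetworks whose global efficiency measures how well the targeted part of
the network exchanges information.

Conventions: both centralities sum over unordered node pairs, so on any
tree they coincide exactly (one unit of flow per pair crosses each
bridging edge).  Self-loops are dropped before every computation here;
cross-component pairs contribute zero to betweenness and efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .io import EdgeKey, Interactome, edge_key


def _simple_graph(g: Interactome) -> nx.Graph:
    return g.to_networkx(include_self_loops=False)


def edge_betweenness(g: Interactome) -> dict[EdgeKey, float]:
    """Shortest-path edge betweenness, unnormalized over unordered pairs.

    c_B(e) = Σ_{u<v} σ(u,v|e) / σ(u,v); disconnected pairs contribute 0.
    """
    G = _simple_graph(g)
    if G.number_of_edges() == 0:
        raise ValueError("graph has no non-self-loop edges")
    raw = nx.edge_betweenness_centrality(G, normalized=False)
    return {edge_key(a, b): v for (a, b), v in raw.items()}

def flow_betweenness(g: Interactome) -> dict[EdgeKey, float]:
    """Current-flow (random-walk) edge betweenness per connected component.

    For every unordered node pair in a component, a unit current is
    injected at one node and extracted at the other; an edge's score is
    the sum over pairs of the absolute current it carries, matching the
    pair-count convention of :func:`edge_betweenness` (exact equality on
    trees).
    """
    G = _simple_graph(g)
    if G.number_of_edges() == 0:
        raise ValueError("graph has no non-self-loop edges")
    out: dict[EdgeKey, float] = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        # networkx's unnormalized variant is half the pairwise current sum.
        raw = nx.edge_current_flow_betweenness_centrality(sub, normalized=False)
        for (a, b), v in raw.items():
            out[edge_key(a, b)] = 2.0 * v
    return out


def centrality_table(g: Interactome) -> pd.DataFrame:
    """Both edge centralities as one table (non-self-loop edges only)."""
    eb = edge_betweenness(g)
    fb = flow_betweenness(g)
    rows = [
        {
            "protein_a": a,
            "protein_b": b,
            "betweenness": eb[(a, b)],
            "flow_betweenness": fb.get((a, b), 0.0),
        }
        for (a, b) in sorted(eb)
    ]
    return pd.DataFrame(rows)


def global_efficiency(g: Interactome) -> float:
    """E(G) = (1/(N(N−1))) Σ_{i≠j} 1/d(i,j) over ordered node pairs.

    Disconnected pairs contribute 0; bounded in [0, 1].
    """
    G = _simple_graph(g)
    if G.number_of_nodes() < 2:
        raise ValueError("efficiency needs at least two nodes")
    return float(nx.global_efficiency(G))


@dataclass
class Subnetwork:
    """A labelled edge subset of a parent interactome."""

    parent: Interactome
    edges: set[EdgeKey]
    label: str

    def __post_init__(self) -> None:
        stray = self.edges - self.parent.edge_keys()
        if stray:
            raise ValueError(f"edges not in parent interactome: {sorted(stray)[:5]}")

    def to_interactome(self) -> Interactome:
        out = Interactome()
        for a, b in sorted(self.edges):
            out.add_edge(a, b)
        return out

    def efficiency(self) -> float:
        return global_efficiency(self.to_interactome())


def disrupted_subnetworks(
    g: Interactome,
    edges_by_label: Mapping[str, Iterable[EdgeKey]],
    shared_edge_policy: str = "exclude",
) -> tuple[Subnetwork, Subnetwork, dict]:
    """Collapse two labels' disrupted edge sets into comparable subnetworks.

    With ``shared_edge_policy='exclude'`` edges disrupted under both labels
    are removed from both subnetworks, isolating label-exclusive rewiring;
    ``'include'`` keeps them in both.  The overlap report carries the
    shared edge set and the gene-set intersection.
    """
    if shared_edge_policy not in ("exclude", "include"):
        raise ValueError(f"unknown shared_edge_policy {shared_edge_policy!r}")
    if len(edges_by_label) != 2:
        raise ValueError("exactly two labels required")
    (la, ea), (lb, eb) = [(l, {edge_key(*e) for e in es})
                          for l, es in edges_by_label.items()]
    shared = ea & eb
    genes_a = {p for e in ea for p in e}
    genes_b = {p for e in eb for p in e}
    if shared_edge_policy == "exclude":
        ea, eb = ea - shared, eb - shared
    report = {
        "shared_edges": sorted(shared),
        "n_shared_edges": len(shared),
        "shared_genes": sorted(genes_a & genes_b),
        "n_shared_genes": len(genes_a & genes_b),
        "shared_edge_policy": shared_edge_policy,
    }
    return Subnetwork(g, ea, la), Subnetwork(g, eb, lb), report


def efficiency_report(sub: Subnetwork) -> dict:
    net = sub.to_interactome()
    return {
        "label": sub.label,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "efficiency": global_efficiency(net) if net.n_nodes >= 2 else 0.0,
    }


def compare_efficiency(a: Subnetwork, b: Subnetwork) -> dict:
    """Global efficiency of two subnetworks and their ratio."""
    ra, rb = efficiency_report(a), efficiency_report(b)
    ratio = ra["efficiency"] / rb["efficiency"] if rb["efficiency"] else float("nan")
    return {a.label: ra, b.label: rb, "efficiency_ratio": ratio}


def compare_centrality(
    g: Interactome,
    edges_a: Iterable[EdgeKey],
    edges_b: Iterable[EdgeKey],
) -> dict:
    """Two-sided Mann-Whitney U on both centralities between two edge sets."""
    ea = {edge_key(*e) for e in edges_a if e[0] != e[1]}
    eb = {edge_key(*e) for e in edges_b if e[0] != e[1]}
    if not ea or not eb:
        raise ValueError("both edge sets must be non-empty (after self-loop removal)")
    tables = {"betweenness": edge_betweenness(g), "flow_betweenness": flow_betweenness(g)}
    out: dict = {}
    for name, table in tables.items():
        xa = [table[e] for e in sorted(ea)]
        xb = [table[e] for e in sorted(eb)]
        u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        out[name] = {
            "U": float(u),
            "p": float(p),
            "median_a": float(pd.Series(xa).median()),
            "median_b": float(pd.Series(xb).median()),
            "n_a": len(xa),
            "n_b": len(xb),
        }
    return out
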