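"""Core domain types and tabular I/O for the interactome pipeline.

Proteins are opaque string tokens (gene symbols or accessions); mapping
between identifier namespaces is the caller's responsibility.  All tables
are tab-separated UTF-8 text with ``#``-prefixed comment lines ignored and
a header row required by default.

Interactions are undirected: ``(a, b)`` and ``(b, a)`` denote the same
edge and are stored canonically with ``a <= b`` lexicographically.
Self-interactions (homo-oligomerization edges) are legal and retained in
the data model; consumers that cannot handle self-loops (path and
random-walk statistics) drop them explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

#: 1000 Genomes-style continental superpopulation codes, in canonical order.
DEFAULT_POPULATIONS: tuple[str, ...] = ("AFR", "AMR", "EAS", "EUR", "SAS")

EdgeKey = tuple[str, str]


def edge_key(a: str, b: str) -> EdgeKey:
    """Canonical unordered key for an interaction between ``a`` and ``b``."""
    return (a, b) if a <= b else (b, a)


def _check_protein_id(token: str) -> str:
    if not token or any(c.isspace() for c in token):
        raise ValueError(f"invalid protein identifier: {token!r}")
    return token


@dataclass(frozen=True)
class Interaction:
    """An undirected protein-protein interaction with source provenance."""

    a: str
    b: str
    sources: frozenset[str] = frozenset()

    @property
    def key(self) -> EdgeKey:
        return edge_key(self.a, self.b)

    @property
    def is_self(self) -> bool:
        return self.a == self.b


class Interactome:
    """An undirected PPI graph: nodes plus canonically keyed edges.

    Duplicate and reversed duplicate edges collapse onto one canonical
    edge whose source-label set is the union of the duplicates'.
    """

    def __init__(self) -> None:
        self.nodes: set[str] = set()
        self._edges: dict[EdgeKey, frozenset[str]] = {}

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self.nodes.add(_check_protein_id(node))

    def add_edge(self, a: str, b: str, sources: Iterable[str] = ()) -> None:
        key = edge_key(_check_protein_id(a), _check_protein_id(b))
        self.nodes.update(key)
        self._edges[key] = self._edges.get(key, frozenset()) | frozenset(sources)

    # -- queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge_keys(self) -> set[EdgeKey]:
        return set(self._edges)

    def sources(self, a: str, b: str) -> frozenset[str]:
        return self._edges[edge_key(a, b)]

    def has_edge(self, a: str, b: str) -> bool:
        return edge_key(a, b) in self._edges

    def edges(self) -> Iterator[Interaction]:
        for (a, b), src in sorted(self._edges.items()):
            yield Interaction(a, b, src)

    def __contains__(self, key: EdgeKey) -> bool:
        return edge_key(*key) in self._edges

    def copy(self) -> "Interactome":
        out = Interactome()
        out.nodes = set(self.nodes)
        out._edges = dict(self._edges)
        return out

    def to_networkx(self, include_self_loops: bool = False) -> nx.Graph:
        """Export to a networkx graph; self-loops dropped by default."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), src in self._edges.items():
            if a == b and not include_self_loops:
                continue
            g.add_edge(a, b, sources=src)
        return g


@dataclass(frozen=True)
class MutationRecord:
    """A missense variant with per-population allele frequencies."""

    variant_id: str
    protein: str
    substitution: str
    allele_freq: Mapping[str, float]

    def present_in(self, population: str) -> bool:
        """Presence rule: strictly non-zero allele frequency."""
        return self.allele_freq[population] > 0.0


def check_populations(populations: Sequence[str]) -> tuple[str, ...]:
    pops = tuple(populations)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if len(set(pops)) != len(pops):
        raise ValueError("population codes must be unique")
    return pops


# ---------------------------------------------------------------------------
# TSV parsing helpers


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_edge_list(
    path: str | Path, source_label: str, header: bool = True
) -> Interactome:
    """Read a two-column (protein_a, protein_b) TSV into an Interactome.

    Every edge is tagged with ``source_label``; duplicates and reversed
    duplicates collapse.  A malformed row raises with its line number.
    """
    out = Interactome()
    first = header
    n_rows = 0
    for lineno, fields in _data_lines(path):
        if first:
            first = False
            continue
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}: malformed edge row at line {lineno}")
        try:
            out.add_edge(fields[0].strip(), fields[1].strip(), [source_label])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        n_rows += 1
    if n_rows == 0:
        warnings.warn(f"{path}: no edges read", stacklevel=2)
    return out


def write_edge_list(interactome: Interactome, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tsource\n")
        for e in interactome.edges():
            fh.write(f"{e.a}\t{e.b}\t{','.join(sorted(e.sources))}\n")


def read_written_edge_list(path: str | Path) -> Interactome:
    """Read an edge list written by :func:`write_edge_list` (keeps sources)."""
    out = Interactome()
    first = True
    for lineno, fields in _data_lines(path):
        if first:
            first = False
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}: malformed edge row at line {lineno}")
        sources = fields[2].split(",") if len(fields) > 2 and fields[2] else []
        out.add_edge(fields[0], fields[1], sources)
    return out


def merge_interactomes(x: Interactome, y: Interactome) -> Interactome:
    """Union of two interactomes; shared edges carry both source-label sets.

    ``|x ∪ y| = |x| + |y| − |x ∩ y|`` by construction.
    """
    out = x.copy()
    out.nodes.update(y.nodes)
    for key, src in y._edges.items():
        out._edges[key] = out._edges.get(key, frozenset()) | src
    return out


def read_mutation_table(
    path: str | Path, populations: Sequence[str] = DEFAULT_POPULATIONS
) -> list[MutationRecord]:
    """Read the variant table with one AF_<POP> column per population."""
    pops = check_populations(populations)
    want = ["variant_id", "protein", "substitution"] + [f"AF_{p}" for p in pops]
    records: list[MutationRecord] = []
    seen: set[str] = set()
    header_map: dict[str, int] | None = None
    for lineno, fields in _data_lines(path):
        if header_map is None:
            header_map = {name: i for i, name in enumerate(fields)}
            missing = [c for c in want if c not in header_map]
            if missing:
                raise ValueError(f"{path}: missing columns {missing}")
            continue
        row = {c: fields[header_map[c]] for c in want}
        vid = row["variant_id"]
        if vid in seen:
            raise ValueError(f"{path}: duplicate variant_id {vid!r} at line {lineno}")
        seen.add(vid)
        freqs: dict[str, float] = {}
        for p in pops:
            col = f"AF_{p}"
            af = float(row[col])
            if not 0.0 <= af <= 1.0:
                raise ValueError(
                    f"{path}: allele frequency out of [0,1] in column {col} "
                    f"at line {lineno}: {af}"
                )
            freqs[p] = af
        records.append(
            MutationRecord(vid, _check_protein_id(row["protein"]),
                           row["substitution"], freqs)
        )
    return records


def write_mutation_table(
    records: Sequence[MutationRecord],
    path: str | Path,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
) -> None:
    pops = check_populations(populations)
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["variant_id", "protein", "substitution"] + [f"AF_{p}" for p in pops]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            afs = "\t".join(format(r.allele_freq[p], "g") for p in pops)
            fh.write(f"{r.variant_id}\t{r.protein}\t{r.substitution}\t{afs}\n")


def read_gene_set(path: str | Path) -> set[str]:
    """One identifier per line; ``#`` comments and blank lines ignored."""
    return {fields[0].strip() for _, fields in _data_lines(path)}


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_lengths(path: str | Path) -> dict[str, int]:
    """Protein sequence lengths TSV: columns protein, length."""
    out: dict[str, int] = {}
    first = True
    for lineno, fields in _data_lines(path):
        if first:
            first = False
            continue
        length = int(fields[1])
        if length <= 0:
            raise ValueError(f"{path}: non-positive length at line {lineno}")
        out[fields[0]] = length
    return out


def write_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tlength\n")
        for p in sorted(lengths):
            fh.write(f"{p}\t{lengths[p]}\n")
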