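"""Seeded synthetic scenario generator for the whole pipeline.

Emulates, at desk scale, the input suite the analysis consumes: two
overlapping interactome edge sources whose union is analyzed; a
population mutation table over the five continental superpopulations with
tunable population privacy; per-(variant, interaction) ΔΔG annotations
drawn from a three-component mixture whose weights hit the configured
effect-class fractions in expectation (detrimental 0.541 / beneficial
0.007 for population variants, 0.762 / 0.014 for a pathogenic set,
matching the class shares the real annotations exhibit); planted disease
modules whose internal edges receive a configurable multiple of the
background detrimental-variant density; protein lengths; cancer and
housekeeping gene-set files; an ortholog dN/dS table realizing configured
per-set median evolutionary rates; and a leveled gene→term map with
planted enriched terms.

Every draw flows from one integer seed; regenerating with the same config
reproduces byte-identical tables.  The generator makes no attempt to
mimic linkage disequilibrium, demography, or realistic site-frequency
spectra — populations are summarized purely by presence/absence plus a
Beta-distributed allele frequency where present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import effects
from .effects import EdgeticAnnotation, annotate, write_annotation_table
from .enrichment import write_term_map
from .evorates import DEFAULT_ORGANISMS, write_ortholog_table
from .io import (DEFAULT_POPULATIONS, Interactome, MutationRecord,
                 write_edge_list, write_gene_set, write_lengths,
                 write_mutation_table)
from .modules import Module
from .rewiring import internal_edges, sample_connected_module


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic scenario; defaults are the study conditions."""

    seed: int = 0
    # interactome
    n_proteins: int = 400
    interactome_model: str = "preferential-attachment"  # or duplication-divergence
    pa_m: int = 3              # preferential-attachment edges per new node
    dd_p: float = 0.4          # duplication-divergence retention probability
    n_self_loops: int = 3      # homo-oligomer self-interactions
    source_overlap: float = 0.33  # |A ∩ B| / |A ∪ B| of the two edge sources
    # population variants
    n_variants: int = 2000
    detrimental_fraction: float = 0.541
    beneficial_fraction: float = 0.007
    privacy: float = 0.5       # fraction of variants private to one population
    presence_prob: float = 0.6  # per-population presence for shared variants
    af_beta: tuple[float, float] = (0.5, 10.0)
    max_extra_annotations: int = 2  # extra PPIs of the host protein per variant
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    # pathogenic comparison set
    n_pathogenic_variants: int = 150
    pathogenic_detrimental_fraction: float = 0.762
    pathogenic_beneficial_fraction: float = 0.014
    # planted disease modules
    n_disease_modules: int = 8
    module_size: int = 20
    planted_density_multiplier: float = 3.0
    # protein lengths
    protein_length_range: tuple[int, int] = (200, 1200)
    # evolutionary rates
    er_medians: Mapping[str, float] = field(
        default_factory=lambda: {"housekeeping": 0.235, "disruptive": 0.223,
                                 "cancer": 0.197})
    er_sd: float = 0.15
    er_genes_per_set: int = 100
    organisms: tuple[str, ...] = DEFAULT_ORGANISMS
    # term map
    n_terms_level3: int = 30
    n_terms_other_levels: int = 8
    term_size_range: tuple[int, int] = (10, 40)
    n_enriched_terms: int = 3
    enrichment_odds: float = 5.0
    query_fraction: float = 0.1

    def validate(self) -> None:
        fr = [self.detrimental_fraction, self.beneficial_fraction,
              self.pathogenic_detrimental_fraction,
              self.pathogenic_beneficial_fraction, self.privacy,
              self.presence_prob, self.source_overlap, self.query_fraction]
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.detrimental_fraction + self.beneficial_fraction > 1:
            raise ValueError("detrimental + beneficial fractions exceed 1")
        if (self.pathogenic_detrimental_fraction
                + self.pathogenic_beneficial_fraction > 1):
            raise ValueError("pathogenic class fractions exceed 1")
        if self.module_size > self.n_proteins:
            raise ValueError("planted module larger than the graph")
        if self.er_genes_per_set * len(self.er_medians) > self.n_proteins:
            raise ValueError("disjoint ER gene sets exceed the protein count")
        if len(self.populations) < 2:
            raise ValueError("need at least two populations")


@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    interactome: Interactome
    source_a: Interactome
    source_b: Interactome
    mutations: list[MutationRecord]
    pathogenic_mutations: list[MutationRecord]
    annotations: list[EdgeticAnnotation]
    pathogenic_annotations: list[EdgeticAnnotation]
    lengths: dict[str, int]
    gene_sets: dict[str, set[str]]
    disease_modules: dict[str, Module]
    disease_seeds: dict[str, set[str]]
    ortholog_table: pd.DataFrame
    term_map: pd.DataFrame
    query_genes: set[str]
    truth: dict

    def write(self, outdir: str | Path) -> dict:
        """Write the full input-file suite plus a manifest with file hashes."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_edge_list(self.source_a, out / "source_a_edges.tsv")
        write_edge_list(self.source_b, out / "source_b_edges.tsv")
        write_mutation_table(self.mutations, out / "mutations.tsv",
                             self.config.populations)
        write_mutation_table(self.pathogenic_mutations,
                             out / "pathogenic_mutations.tsv",
                             self.config.populations)
        write_annotation_table(self.annotations, out / "annotations.tsv")
        write_annotation_table(self.pathogenic_annotations,
                               out / "pathogenic_annotations.tsv")
        write_lengths(self.lengths, out / "lengths.tsv")
        for name, genes in sorted(self.gene_sets.items()):
            write_gene_set(genes, out / f"genes_{name}.txt")
        for mid, seeds in sorted(self.disease_seeds.items()):
            write_gene_set(seeds, out / f"seeds_{mid}.txt")
        write_ortholog_table(self.ortholog_table, out / "orthologs.tsv")
        write_term_map(self.term_map, out / "terms.tsv")
        write_gene_set(self.query_genes, out / "query_genes.txt")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        manifest = {
            "config": _config_dict(self.config),
            "files": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.iterdir()) if p.name != "manifest.json"
            },
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def _config_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["er_medians"] = dict(d["er_medians"])
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _make_graph(config: ScenarioConfig, seed: int) -> Interactome:
    n = config.n_proteins
    if config.interactome_model == "preferential-attachment":
        g = nx.barabasi_albert_graph(n, config.pa_m, seed=seed)
    elif config.interactome_model == "duplication-divergence":
        g = nx.duplication_divergence_graph(n, config.dd_p, seed=seed)
    else:
        raise ValueError(f"unknown interactome model "
                         f"{config.interactome_model!r}")
    width = len(str(n - 1))
    mapping = {i: f"P{i:0{width}d}" for i in g.nodes}
    out = Interactome()
    for u, v in g.edges:
        out.add_edge(mapping[u], mapping[v])
    for node in mapping.values():
        out.add_node(node)
    return out


def _split_sources(
    union: Interactome, overlap: float, rng: np.random.Generator
) -> tuple[Interactome, Interactome]:
    edges = sorted(union.edge_keys())
    n = len(edges)
    n_both = round(overlap * n)
    order = rng.permutation(n)
    both = [edges[i] for i in order[:n_both]]
    rest = [edges[i] for i in order[n_both:]]
    half = len(rest) // 2
    a, b = Interactome(), Interactome()
    for e in both:
        a.add_edge(*e, sources=["sourceA"])
        b.add_edge(*e, sources=["sourceB"])
    for e in rest[:half]:
        a.add_edge(*e, sources=["sourceA"])
    for e in rest[half:]:
        b.add_edge(*e, sources=["sourceB"])
    return a, b


def _draw_ddg(cls: str, rng: np.random.Generator) -> float:
    # Component means sit away from the ±0.5 boundaries; values are clipped
    # a margin beyond them so class labels never flip on rounding.
    if cls == effects.DETRIMENTAL:
        return float(max(0.55, rng.normal(1.5, 0.4)))
    if cls == effects.BENEFICIAL:
        return float(min(-0.55, rng.normal(-1.3, 0.35)))
    return float(np.clip(rng.normal(0.0, 0.18), -0.45, 0.45))


def _presence_row(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[dict[str, float], bool]:
    """Per-population allele frequencies for one variant; returns (AFs, private)."""
    pops = config.populations
    a, b = config.af_beta
    private = bool(rng.random() < config.privacy)
    if private:
        present = {pops[rng.integers(len(pops))]}
    else:
        present = {p for p in pops if rng.random() < config.presence_prob}
        if not present:
            present = {pops[rng.integers(len(pops))]}
    freqs = {}
    for p in pops:
        if p in present:
            af = float(rng.beta(a, b))
            freqs[p] = round(max(af, 1e-4), 6)
        else:
            freqs[p] = 0.0
    return freqs, private


def _substitution(rng: np.random.Generator, length: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    i, j = rng.integers(len(aas)), rng.integers(len(aas))
    pos = int(rng.integers(1, length + 1))
    return f"{aas[i]}{pos}{aas[j]}"


def _variant_tables(
    config: ScenarioConfig,
    union: Interactome,
    module_internal: list,
    rng: np.random.Generator,
) -> tuple[list[MutationRecord], list[tuple], dict]:
    """Population variant table plus raw annotation rows with planted density."""
    edges = sorted(union.edge_keys())
    n_edges = len(edges)
    internal = sorted(set(module_internal))
    # Weight detrimental variants toward module-internal edges so their
    # per-edge detrimental density is `multiplier` times the background.
    m = config.planted_density_multiplier
    r = len(internal) / n_edges if n_edges else 0.0
    w = (m - 1) * r / (1 + (m - 1) * r) if internal and m > 1 else 0.0
    classes = rng.choice(
        [effects.DETRIMENTAL, effects.BENEFICIAL, effects.NEUTRAL],
        size=config.n_variants,
        p=[config.detrimental_fraction, config.beneficial_fraction,
           1 - config.detrimental_fraction - config.beneficial_fraction],
    )
    lengths_provisional: dict[str, int] = {}
    records, rows = [], []
    n_private = 0
    provenances = ["native", "full_model", "ddi_model"]
    incident: dict[str, list] = {}
    for e in edges:
        incident.setdefault(e[0], []).append(e)
        incident.setdefault(e[1], []).append(e)
    for i in range(config.n_variants):
        cls = classes[i]
        if cls == effects.DETRIMENTAL and internal and rng.random() < w:
            edge = internal[rng.integers(len(internal))]
        else:
            edge = edges[rng.integers(n_edges)]
        protein = edge[rng.integers(2)] if edge[0] != edge[1] else edge[0]
        vid = f"rs{900000 + i}"
        freqs, private = _presence_row(config, rng)
        n_private += private
        length = lengths_provisional.setdefault(
            protein, int(rng.integers(*config.protein_length_range)))
        records.append(MutationRecord(vid, protein, _substitution(rng, length),
                                      freqs))
        prov = provenances[rng.integers(3)]
        rows.append((vid, edge, _draw_ddg(cls, rng), prov))
        # The same variant may be annotated against other PPIs of its protein.
        others = [e for e in incident[protein] if e != edge]
        n_extra = int(rng.integers(0, config.max_extra_annotations + 1))
        for _ in range(min(n_extra, len(others))):
            extra = others[rng.integers(len(others))]
            rows.append((vid, extra, _draw_ddg(cls, rng),
                         provenances[rng.integers(3)]))
    truth_part = {
        "class_counts": {c: int((classes == c).sum())
                         for c in effects.EFFECT_CLASSES},
        "n_private_variants": n_private,
        "planted_weight_internal": w,
    }
    return records, rows, truth_part


def _pathogenic_tables(
    config: ScenarioConfig, union: Interactome, rng: np.random.Generator
) -> tuple[list[MutationRecord], list[tuple], dict]:
    edges = sorted(union.edge_keys())
    classes = rng.choice(
        [effects.DETRIMENTAL, effects.BENEFICIAL, effects.NEUTRAL],
        size=config.n_pathogenic_variants,
        p=[config.pathogenic_detrimental_fraction,
           config.pathogenic_beneficial_fraction,
           1 - config.pathogenic_detrimental_fraction
           - config.pathogenic_beneficial_fraction],
    )
    records, rows = [], []
    for i in range(config.n_pathogenic_variants):
        edge = edges[rng.integers(len(edges))]
        protein = edge[rng.integers(2)] if edge[0] != edge[1] else edge[0]
        vid = f"path_rs{100000 + i}"
        freqs, _ = _presence_row(config, rng)
        records.append(MutationRecord(vid, protein, _substitution(rng, 500),
                                      freqs))
        rows.append((vid, edge, _draw_ddg(classes[i], rng), "native"))
    truth = {"pathogenic_class_counts":
             {c: int((classes == c).sum()) for c in effects.EFFECT_CLASSES}}
    return records, rows, truth


def _ortholog_table(
    config: ScenarioConfig, proteins: Sequence[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    # Sets are disjoint so each gene carries exactly one planted median;
    # downstream comparisons may still union them freely.
    perm = rng.permutation(list(proteins))
    sets: dict[str, set[str]] = {}
    rows = []
    for i, name in enumerate(sorted(config.er_medians)):
        median = config.er_medians[name]
        genes = perm[i * config.er_genes_per_set:
                     (i + 1) * config.er_genes_per_set]
        sets[name] = set(map(str, genes))
        for gene in genes:
            base = rng.normal(median, config.er_sd)
            for org in config.organisms:
                ratio = max(base + rng.normal(0.0, 0.02), 1e-3)
                ds = round(float(rng.uniform(0.05, 0.5)), 6)
                rows.append({"gene": gene, "organism": org,
                             "dn": round(ratio * ds, 6), "ds": ds})
    return pd.DataFrame(rows), sets


def _term_map(
    config: ScenarioConfig,
    proteins: Sequence[str],
    query: set[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    proteins = sorted(proteins)
    weights = np.array([config.enrichment_odds if p in query else 1.0
                        for p in proteins])
    weights = weights / weights.sum()
    namespaces = ["BP", "MF", "CC"]
    rows, enriched = [], []
    term_no = 0
    for level, n_terms in ((2, config.n_terms_other_levels),
                           (3, config.n_terms_level3),
                           (4, config.n_terms_other_levels)):
        for j in range(n_terms):
            term = f"T{term_no:04d}"
            term_no += 1
            size = int(rng.integers(*config.term_size_range))
            planted = level == 3 and j < config.n_enriched_terms
            if planted:
                genes = rng.choice(proteins, size=size, replace=False, p=weights)
                enriched.append(term)
            else:
                genes = rng.choice(proteins, size=size, replace=False)
            ns = namespaces[term_no % 3]
            for gene in sorted(map(str, genes)):
                rows.append({"gene": gene, "term": term, "level": level,
                             "namespace": ns})
    return pd.DataFrame(rows), enriched


def generate(config: ScenarioConfig) -> SyntheticScenario:
    """Generate a full scenario deterministically from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    graph_seed = int(rng.integers(2**31 - 1))
    union = _make_graph(config, graph_seed)
    nodes = sorted(union.nodes)
    for _ in range(config.n_self_loops):
        node = nodes[rng.integers(len(nodes))]
        union.add_edge(node, node)
    source_a, source_b = _split_sources(union, config.source_overlap, rng)

    G = union.to_networkx(include_self_loops=False)
    disease_modules: dict[str, Module] = {}
    disease_seeds: dict[str, set[str]] = {}
    module_internal: list = []
    for i in range(config.n_disease_modules):
        members = sample_connected_module(G, config.module_size, rng)
        mid = f"D{i:02d}"
        disease_modules[mid] = Module(members, "seeded")
        picks = sorted(members)
        k = max(2, len(picks) // 2)
        idx = rng.choice(len(picks), size=k, replace=False)
        disease_seeds[mid] = {picks[j] for j in sorted(idx)}
        module_internal.extend(internal_edges(union, members))

    mutations, rows, truth_pop = _variant_tables(config, union,
                                                 module_internal, rng)
    path_mutations, path_rows, truth_path = _pathogenic_tables(config, union,
                                                               rng)
    annotations = annotate(rows, union, mutations)
    path_annotations = annotate(path_rows, union, path_mutations)

    lengths = {p: int(rng.integers(*config.protein_length_range))
               for p in nodes}
    # Host proteins keep the provisional length their substitutions used.
    for m in mutations + path_mutations:
        pos = int("".join(c for c in m.substitution[1:-1]))
        lengths[m.protein] = max(lengths.get(m.protein, 0), pos)

    ortholog_table, er_sets = _ortholog_table(config, nodes, rng)
    gene_sets = {}
    for name in ("cancer", "housekeeping"):
        if name in er_sets:
            gene_sets[name] = er_sets[name]
        else:  # custom ER set names: fall back to fresh random gene sets
            idx = rng.choice(len(nodes), size=min(50, len(nodes)),
                             replace=False)
            gene_sets[name] = {nodes[i] for i in sorted(idx)}

    n_query = max(5, round(config.query_fraction * len(nodes)))
    query_idx = rng.choice(len(nodes), size=n_query, replace=False)
    query = {nodes[i] for i in sorted(query_idx)}
    term_map, enriched_terms = _term_map(config, nodes, query, rng)

    truth = {
        "seed": config.seed,
        "n_union_edges": union.n_edges,
        "n_source_a": source_a.n_edges,
        "n_source_b": source_b.n_edges,
        "n_shared_edges": len(source_a.edge_keys() & source_b.edge_keys()),
        "detrimental_fraction_target": config.detrimental_fraction,
        "beneficial_fraction_target": config.beneficial_fraction,
        "planted_density_multiplier": config.planted_density_multiplier,
        "disease_modules": {k: sorted(v.members)
                            for k, v in disease_modules.items()},
        "er_medians": dict(config.er_medians),
        "er_sets": {k: sorted(v) for k, v in er_sets.items()},
        "enriched_terms": enriched_terms,
        "enrichment_odds": config.enrichment_odds,
        "privacy": config.privacy,
        **truth_pop,
        **truth_path,
    }
    return SyntheticScenario(
        config=config, interactome=union, source_a=source_a, source_b=source_b,
        mutations=mutations, pathogenic_mutations=path_mutations,
        annotations=annotations, pathogenic_annotations=path_annotations,
        lengths=lengths, gene_sets=gene_sets, disease_modules=disease_modules,
        disease_seeds=disease_seeds, ortholog_table=ortholog_table,
        term_map=term_map, query_genes=query, truth=truth,
    )


def truth_report(scenario: SyntheticScenario) -> dict:
    """Machine-readable planted parameters for downstream recovery tests."""
    return dict(scenario.truth)
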