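"""Stage orchestration: wire the library modules into a file-based pipeline.

Each stage reads its inputs from paths named in a single config mapping,
runs the corresponding library calls, and writes deterministic TSV/JSON
artifacts into the output directory.  Stages recompute shared
prerequisites lazily and cache them in memory, so ``run("all", ...)``
does each computation once; rerunning with an identical config and seed
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__, effects, enrichment, evorates, io, modules
from . import netstats, profiles, rewiring, synth

log = logging.getLogger("edgetics")

STAGES = ("annotate", "profiles", "netstats", "modules", "rewiring",
          "evorates", "enrich", "simulate", "all")

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "permutation_R": 1000,
    "dsd_k": 5,
    "n_clusters": None,          # default: helper targeting mean size 20
    "target_module_size": 20,
    "size_range": [3, 100],
    "max_added": 20,
    "alpha": 0.01,
    "term_level": 3,
    "pair_normalization": "ordered",
    "shared_edge_policy": "exclude",
    "n_profile_proteins": 25,    # cap on proteins profiled per run
}


def default_config(input_dir: str | Path, outdir: str | Path,
                   seed: int = 0) -> dict:
    """A config pointing at a directory written by the synthetic generator."""
    d = Path(input_dir)
    return {
        "seed": seed,
        "outdir": str(outdir),
        "populations": list(io.DEFAULT_POPULATIONS),
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "inputs": {
            "source_a": str(d / "source_a_edges.tsv"),
            "source_a_label": "sourceA",
            "source_b": str(d / "source_b_edges.tsv"),
            "source_b_label": "sourceB",
            "mutations": str(d / "mutations.tsv"),
            "pathogenic_mutations": str(d / "pathogenic_mutations.tsv"),
            "annotations": str(d / "annotations.tsv"),
            "pathogenic_annotations": str(d / "pathogenic_annotations.tsv"),
            "lengths": str(d / "lengths.tsv"),
            "orthologs": str(d / "orthologs.tsv"),
            "terms": str(d / "terms.tsv"),
            "gene_sets": {
                "cancer": str(d / "genes_cancer.txt"),
                "housekeeping": str(d / "genes_housekeeping.txt"),
            },
            "disease_seeds": {
                p.stem.removeprefix("seeds_"): str(p)
                for p in sorted(d.glob("seeds_*.txt"))
            },
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    cfg.setdefault("thresholds", {})
    for k, v in DEFAULT_THRESHOLDS.items():
        cfg["thresholds"].setdefault(k, v)
    cfg.setdefault("populations", list(io.DEFAULT_POPULATIONS))
    cfg.setdefault("seed", 0)
    return cfg


def _require(config: Mapping, key: str) -> str:
    path = config.get("inputs", {}).get(key)
    if path is None:
        raise FileNotFoundError(f"config names no input path for {key!r}")
    if not Path(path).exists():
        raise FileNotFoundError(f"missing input file for {key!r}: {path}")
    return path


class Pipeline:
    """Lazy, cached execution of the analysis stages for one config."""

    def __init__(self, config: Mapping):
        self.config = config
        self.outdir = Path(config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.populations = list(config.get("populations",
                                           io.DEFAULT_POPULATIONS))
        self.t = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
        self.seed = int(config.get("seed", 0))
        self._cache: dict[str, Any] = {}

    # -- cached prerequisites -----------------------------------------
    def _get(self, key: str, build):
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def interactome(self) -> io.Interactome:
        def build():
            a = io.read_edge_list(_require(self.config, "source_a"),
                                  self.config["inputs"].get("source_a_label",
                                                            "sourceA"))
            b = io.read_edge_list(_require(self.config, "source_b"),
                                  self.config["inputs"].get("source_b_label",
                                                            "sourceB"))
            merged = io.merge_interactomes(a, b)
            log.info("interactome: %d nodes, %d edges (A=%d, B=%d)",
                     merged.n_nodes, merged.n_edges, a.n_edges, b.n_edges)
            return merged
        return self._get("interactome", build)

    @property
    def mutations(self):
        return self._get("mutations", lambda: io.read_mutation_table(
            _require(self.config, "mutations"), self.populations))

    @property
    def annotations(self):
        def build():
            rows = effects.read_annotation_rows(
                _require(self.config, "annotations"))
            return effects.annotate(rows, self.interactome, self.mutations)
        return self._get("annotations", build)

    @property
    def pathogenic_annotations(self):
        def build():
            rows = effects.read_annotation_rows(
                _require(self.config, "pathogenic_annotations"))
            muts = io.read_mutation_table(
                _require(self.config, "pathogenic_mutations"),
                self.populations)
            return effects.annotate(rows, self.interactome, muts)
        return self._get("pathogenic_annotations", build)

    @property
    def enriched(self) -> set[str]:
        def build():
            lengths = io.read_lengths(_require(self.config, "lengths"))
            rates = effects.disruptive_rates(self.annotations, lengths)
            return effects.enriched_genes(rates)
        return self._get("enriched", build)

    @property
    def topology_modules(self):
        def build():
            G = self.interactome.to_networkx()
            import networkx as nx
            comp = max(nx.connected_components(G), key=len)
            sub = io.Interactome()
            for u, v in G.subgraph(comp).edges:
                sub.add_edge(u, v)
            dsd = modules.dsd_matrix(sub, k=self.t["dsd_k"])
            n_clusters = self.t["n_clusters"] or modules.n_clusters_for_target_size(
                sub.n_nodes, self.t["target_module_size"])
            return modules.spectral_modules(
                dsd, n_clusters, tuple(self.t["size_range"]), seed=self.seed)
        return self._get("topology_modules", build)

    @property
    def disease_modules(self) -> dict[str, modules.Module]:
        def build():
            seeds_cfg = self.config.get("inputs", {}).get("disease_seeds", {})
            if not seeds_cfg:
                raise FileNotFoundError("config names no disease_seeds inputs")
            out = {}
            for mid, path in sorted(seeds_cfg.items()):
                if not Path(path).exists():
                    raise FileNotFoundError(
                        f"missing input file for disease_seeds[{mid}]: {path}")
                seeds = io.read_gene_set(path) & self.interactome.nodes
                out[mid] = modules.diamond_expand(
                    self.interactome, seeds, max_added=self.t["max_added"])
            return out
        return self._get("disease_modules", build)

    # -- stages -------------------------------------------------------
    def stage_annotate(self) -> list[str]:
        lengths = io.read_lengths(_require(self.config, "lengths"))
        ann = self.annotations
        io.write_edge_list(self.interactome, self.outdir / "interactome.tsv")
        effects.write_annotation_table(ann, self.outdir / "annotations_validated.tsv")
        effects.effect_summary(ann, self.mutations).to_csv(
            self.outdir / "effect_summary.tsv", sep="\t", index=False)
        rates = effects.disruptive_rates(ann, lengths)
        rates.to_csv(self.outdir / "disruptive_rates.tsv", sep="\t", index=False)
        io.write_gene_set(effects.enriched_genes(rates),
                          self.outdir / "enriched_genes.txt")
        io.write_gene_set(effects.disruptive_genes(ann),
                          self.outdir / "disruptive_genes.txt")
        return ["interactome.tsv", "annotations_validated.tsv",
                "effect_summary.tsv", "disruptive_rates.tsv",
                "enriched_genes.txt", "disruptive_genes.txt"]

    def stage_profiles(self) -> list[str]:
        det_by_protein: dict[str, int] = {}
        for a in self.annotations:
            if a.effect == effects.DETRIMENTAL:
                det_by_protein[a.protein] = det_by_protein.get(a.protein, 0) + 1
        candidates = sorted(self.enriched & set(det_by_protein)) or \
            sorted(det_by_protein)
        cap = self.t["n_profile_proteins"]
        chosen = sorted(candidates, key=lambda p: -det_by_protein[p])[:cap]
        profs = {
            p: profiles.build_profiles(self.annotations, self.mutations, p,
                                       self.populations)
            for p in sorted(chosen)
        }
        profiles.write_profiles(profs, self.outdir / "profiles.tsv")
        result = profiles.permutation_test(
            profs, R=self.t["permutation_R"], seed=self.seed,
            pair_normalization=self.t["pair_normalization"])
        with open(self.outdir / "profile_divergence.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        return ["profiles.tsv", "profile_divergence.json"]

    def stage_netstats(self) -> list[str]:
        pop_edges = effects.disrupted_edges(self.annotations)
        path_edges = effects.disrupted_edges(self.pathogenic_annotations)
        sub_path, sub_pop, overlap = netstats.disrupted_subnetworks(
            self.interactome,
            {"pathogenic": path_edges, "population": pop_edges},
            shared_edge_policy=self.t["shared_edge_policy"])
        netstats.centrality_table(self.interactome).to_csv(
            self.outdir / "edge_centrality.tsv", sep="\t", index=False)
        report = {
            "overlap": {k: v for k, v in overlap.items()
                        if not k.startswith("shared_edges")},
            "efficiency": netstats.compare_efficiency(sub_path, sub_pop),
        }
        loops = {e for e in pop_edges | path_edges if e[0] == e[1]}
        pa = {e for e in sub_path.edges if e[0] != e[1]}
        po = {e for e in sub_pop.edges if e[0] != e[1]}
        if pa and po:
            report["centrality_comparison"] = netstats.compare_centrality(
                self.interactome, pa, po)
        report["n_self_loop_edges_excluded"] = len(loops)
        with open(self.outdir / "netstats.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return ["edge_centrality.tsv", "netstats.json"]

    def stage_modules(self) -> list[str]:
        modules.write_modules(self.topology_modules,
                              self.outdir / "topology_modules.tsv")
        artifacts = ["topology_modules.tsv"]
        for mid, module in sorted(self.disease_modules.items()):
            fname = f"diamond_{mid}.tsv"
            modules.write_diamond_trace(module, self.outdir / fname)
            artifacts.append(fname)
        modules.write_modules(list(self.disease_modules.values()),
                              self.outdir / "disease_modules.tsv")
        artifacts.append("disease_modules.tsv")
        return artifacts

    def stage_rewiring(self) -> list[str]:
        disrupted = effects.disrupted_edges(self.annotations)
        observed = self.topology_modules
        null = rewiring.random_module_null(self.interactome, observed,
                                           seed=self.seed)
        obs_t = rewiring.density_table(self.interactome, observed, disrupted,
                                       "observed")
        null_t = rewiring.density_table(self.interactome, null, disrupted,
                                        "null")
        import pandas as pd
        pd.concat([obs_t, null_t]).to_csv(self.outdir / "rewiring_density.tsv",
                                          sep="\t", index=False)
        test = rewiring.module_enrichment_test(obs_t["density"].tolist(),
                                               null_t["density"].tolist())
        prev = rewiring.prevalence_matrix(
            self.interactome, self.disease_modules, self.annotations,
            self.mutations, self.populations)
        prev.to_csv(self.outdir / "prevalence_matrix.tsv", sep="\t",
                    index_label="module_id")
        order = rewiring.hierarchical_order(prev)
        with open(self.outdir / "rewiring.json", "w") as fh:
            json.dump({"module_enrichment": test, "ordering": order}, fh,
                      indent=2, sort_keys=True)
        return ["rewiring_density.tsv", "prevalence_matrix.tsv",
                "rewiring.json"]

    def stage_evorates(self) -> list[str]:
        table = evorates.read_ortholog_table(_require(self.config, "orthologs"))
        ers = evorates.gene_er(table)
        ers.to_csv(self.outdir / "gene_er.tsv", sep="\t", index=False)
        sets = {"disruptive": effects.disruptive_genes(self.annotations)}
        for name, path in self.config.get("inputs", {}).get(
                "gene_sets", {}).items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"missing input file for gene_sets[{name}]: {path}")
            sets[name] = io.read_gene_set(path)
        report = {}
        names = sorted(sets)
        for i, na in enumerate(names):
            for nb in names[i + 1:]:
                ea = ers[ers["gene"].isin(sets[na])]
                eb = ers[ers["gene"].isin(sets[nb])]
                if len(ea) >= 2 and len(eb) >= 2:
                    report[f"{na}_vs_{nb}"] = evorates.compare_er(ea, eb)
        with open(self.outdir / "er_comparison.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return ["gene_er.tsv", "er_comparison.json"]

    def stage_enrich(self) -> list[str]:
        terms = enrichment.read_term_map(_require(self.config, "terms"))
        universe = {a.protein for a in self.annotations}
        query = self.enriched & universe
        if not query:
            query = effects.disruptive_genes(self.annotations) & universe
        table = enrichment.enrich(query, universe, terms,
                                  level=self.t["term_level"],
                                  alpha=self.t["alpha"])
        table.to_csv(self.outdir / "term_enrichment.tsv", sep="\t",
                     index=False)
        return ["term_enrichment.tsv"]

    def stage_simulate(self) -> list[str]:
        scen_cfg = synth.ScenarioConfig(
            **{**self.config.get("scenario", {}), "seed": self.seed})
        scenario = synth.generate(scen_cfg)
        manifest = scenario.write(self.outdir / "inputs")
        with open(self.outdir / "scenario_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return ["inputs", "scenario_manifest.json"]


def run(stage: str, config: Mapping) -> list[str]:
    """Run one stage (or ``all``); returns the artifact names written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    pipe = Pipeline(config)
    if stage == "all":
        artifacts = []
        for s in ("annotate", "profiles", "netstats", "modules", "rewiring",
                  "evorates", "enrich"):
            log.info("stage %s", s)
            artifacts += getattr(pipe, f"stage_{s}")()
    else:
        artifacts = getattr(pipe, f"stage_{stage}")()
    manifest = {
        "stage": stage,
        "seed": pipe.seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": sorted(artifacts),
    }
    with open(pipe.outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return artifacts
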