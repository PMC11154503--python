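"""Are disease modules hotspots of interaction-disrupting variation?

Each module's rewired-edge density (disrupted internal edges per member
node) is compared against size-matched random connected modules; the
module x population prevalence matrix then shows where that rewiring
concentrates geographically.
"""

from edgetics import synth
from edgetics.effects import disrupted_edges
from edgetics.rewiring import (density_table, hierarchical_order,
                               module_enrichment_test, prevalence_matrix,
                               random_module_null)

cfg = synth.ScenarioConfig(seed=8, n_proteins=300, n_variants=600,
                           n_pathogenic_variants=20, n_disease_modules=10,
                           module_size=12, planted_density_multiplier=3.0,
                           er_genes_per_set=60)
scenario = synth.generate(cfg)
g = scenario.interactome
disrupted = disrupted_edges(scenario.annotations)

observed = list(scenario.disease_modules.values())
null = random_module_null(g, observed, seed=1)
obs_d = density_table(g, observed, disrupted, "observed")["density"]
null_d = density_table(g, null, disrupted, "null")["density"]
rep = module_enrichment_test(obs_d.tolist(), null_d.tolist())
print(f"median rewired density: modules {rep['median_observed']:.2f} "
      f"vs random {rep['median_null']:.2f}")
print(f"one-sided Mann-Whitney p = {rep['p']:.4f}")

prev = prevalence_matrix(g, scenario.disease_modules, scenario.annotations,
                         scenario.mutations)
print("\nmodule x population rewiring prevalence:")
print(prev.round(2).to_string())
order = hierarchical_order(prev)
print("\nhierarchically clustered row order:", order["row_order"])
print("hierarchically clustered col order:", order["col_order"])
# The planted 3x density shows up as a small enrichment p-value; the
# prevalence matrix is what a heatmap figure would render, with rows and
# columns pre-ordered by average-linkage clustering.
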