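# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind the `edgetics` package, in the order the pipeline runs.

## Data model and interactome construction

Proteins are opaque string tokens; identifier mapping (gene symbol ↔
UniProt accession) is deliberately the caller's problem, since any mapping
pipeline is dataset-specific. Interactions are undirected and stored
canonically with endpoints sorted, so duplicate and reversed rows collapse
on read. Self-interactions (homo-oligomers such as an ALDH2–ALDH2 edge)
are first-class citizens of the data model and count in rewiring
statistics, but are dropped from every path-based and random-walk
computation (betweenness, efficiency, DSD, DIAMOnD), where a self-loop has
no meaning. Merging two edge sources takes the union of edge sets and the
union of per-edge source labels, so `|x ∪ y| = |x| + |y| − |x ∩ y|` holds
structurally.

All tables are tab-separated UTF-8 with `#` comments and a required header;
writers emit the same dialect byte-stably, so rerunning any stage with
identical inputs and seeds reproduces identical files.

## Effect classification

ΔΔG = ΔG_mut − ΔG_wt in kcal/mol, classified at the conventional ±0.5
thresholds (beneficial < −0.5 ≤ neutral < 0.5 ≤ detrimental). The
boundaries are closed on the neutral side at −0.5 and on the detrimental
side at +0.5. When one (variant, interaction) pair carries ΔΔG values from
several structural sources, the priority is native structure > full-complex
model > domain–domain model; the class is always recomputed from the
winning ΔΔG, never trusted from an input column.

Summary fractions use "at least one PPI" semantics per class: a variant
detrimental to one interaction and beneficial to another counts in both
classes, so the three per-variant percentages need not sum to 100 (the
per-annotation counts do). Reported percentages round half-up to one
decimal. The disruptive-rate enrichment cut-off uses the gene-weighted mean
and the sample (n−1) standard deviation; the sample estimator is the
conservative choice for small tables, and gene weighting treats the
proteome, not the variant pool, as the background. With all rates identical
(zero SD) no gene is called enriched and a warning is emitted.

Per-gene detrimental counts are *distinct detrimental variants on the
protein*, not (variant, interaction) pairs, so a variant disrupting two
interactions of its host counts once toward the host's rate.

## Edgetic profiles and the divergence test

The position space of a protein is the ordered set of its detrimental
(interaction, variant) pairs — interactions sorted by canonical edge key,
variants by id — shared by all populations, so profiles are directly
comparable. Interaction-preserving (neutral and beneficial) annotations are
excluded from profiles. Presence is allele frequency strictly > 0; no
minimum-frequency filter is applied.

Two pair-normalization conventions exist for the cross-population average:
the default divides the unordered-pair sum by N(N−1) ("ordered", matching
the printed form of the formula), the alternative by N(N−1)/2 (a true
pairwise mean, exactly 2× larger). Results carry a label saying which was
used.

The permutation test shuffles each population's bit vector independently
within the protein's position space, preserving each population's mutation
burden (popcount) while destroying cross-population correlation in *which*
positions are hit. The protein-level statistic is the unweighted mean over
proteins. The empirical p-value is the add-one upper tail
(1 + #{null ≥ obs})/(1 + R); the z-score uses the sample SD of the null and
is reported as NaN when the null is degenerate (e.g., all-zero profiles).
One `numpy` generator seeded once drives all R replicates.

Directionality note: co-presence of shared variants across populations
*lowers* observed divergence below the shuffle null, while
population-private variants raise it above. The synthetic default (privacy
0.5) therefore sits below the null — the upper-tail test correctly does not
reject — and power against the test is assessed on fully private
configurations, which is also the regime the analysis is designed to
detect.

## Network statistics

Both edge centralities use unordered-pair normalization, so on trees
current-flow betweenness equals shortest-path betweenness exactly (a useful
internal consistency check: one unit of flow per pair crosses each bridge).
`networkx` supplies both computations; its unnormalized current-flow value
is half the pairwise current sum and is rescaled accordingly. Current
conservation holds to the solver's tolerance (~1e−9 in the test oracles'
Laplacian-pseudoinverse formulation). Disconnected node pairs contribute
zero to betweenness and efficiency rather than erroring — the merged
interactome is not guaranteed connected.

Disrupted subnetworks collapse each label's detrimentally hit edges; with
the default `exclude` policy, edges disrupted under both labels are removed
from both, isolating label-exclusive rewiring. Subnetwork efficiency is
computed on the subnetwork's own node set (endpoints of its edges);
self-loops and thus self-loop-only singleton nodes are excluded.
Centrality comparisons between edge sets use a two-sided Mann–Whitney U.

## Module detection

DSD uses the finite-k definition with the start visit counted:
D_k = Σ_{t=0..k} row(P^t) with P the degree-normalized transition matrix,
so each row sums to k+1 exactly. The default k = 5 is deep enough to see
community structure on desk-scale graphs while staying cheap; the converged
(k→∞) variant is out of scope. Cross-component distances are infinite,
which the clustering affinity maps to zero.

Spectral clustering operates on affinity exp(−DSD²/(2σ²)) with σ the median
finite off-diagonal DSD — a standard scale-free bandwidth choice. The
cluster count is a required knob; a helper derives it from a target mean
module size (total nodes / target). Clusters outside the 3–100 size range
are discarded. The k-means step takes an explicit seed.

DIAMOnD scores an outside node of degree k with ks links into the s0
current members by the hypergeometric upper tail of drawing ≥ ks members
among its k neighbor choices from the other N−1 nodes. Ties break by
higher ks, then lower degree, then lexicographic id, making expansion fully
deterministic. Seed weighting (the original α) is fixed at 1. Expansion
stops after `max_added` additions (default 100 in the library, smaller in
desk-scale configs) or when no candidate touches the module.

## Module rewiring and prevalence

Rewired density is (disrupted module-internal edges)/(module nodes) — the
node-count denominator keeps the published statistic — while the
module × population prevalence matrix defaults to the edge-count
denominator, where a cell reads directly as "fraction of the module's
interactions rewired in this population"; both denominators are available.
Edge-free modules yield missing prevalence cells, which are excluded from
testing and zero-imputed only for dendrogram ordering.

Null modules are size-matched connected subgraphs grown by seeded random
neighborhood expansion, controlling for the connectivity that observed
modules have by construction; a uniform node-sampling null is available
behind a flag. Enrichment is a one-sided (observed > null) Mann–Whitney U.
Hierarchical ordering uses average-linkage on Euclidean distances with
rows/columns pre-sorted by label, so the dendrogram is invariant to input
permutation.

## Evolutionary rates and term enrichment

Per (gene, organism): dN/dS computed per ortholog row, rows with missing
values or dS = 0 dropped (dN = 0 is a valid zero ratio), paralog rows
averaged into one organism value. Genes need orthologs in **more than
three** organisms (strict) to receive an ER, the unweighted organism mean.
The filtering order (drop → ratio → group → count → threshold) is fixed and
regression-tested. Set comparisons use the two-sample Wilcoxon rank-sum
(Mann–Whitney) form — the sets are independent gene collections, so the
signed-rank variant would be meaningless — with overlapping sets compared
as given.

Term enrichment is a plain hypergeometric upper tail per term at the chosen
hierarchy level (default 3) with BH q-values; the EASE-style modified score
of some hosted services is intentionally not replicated. Significance
flags use raw p ≤ 0.01, with q-values alongside. Term levels are an input
column; no ontology DAG is parsed.

## Synthetic scenarios

Defaults (one seed drives everything; identical configs produce
byte-identical files):

| parameter | default | rationale |
|---|---|---|
| n_proteins / model | 400, preferential attachment (m=3) | scale-free degree structure at desk scale; duplication–divergence available |
| source overlap | 0.33 of the union | matches the overlap regime of two complementary curated PPI sources |
| n_variants | 2000 | large enough for stable class fractions, small enough for seconds-scale runs |
| detrimental / beneficial fraction | 0.541 / 0.007 | class shares observed in population-scale annotation |
| pathogenic detrimental / beneficial | 0.762 / 0.014 | class shares observed for pathogenic variants |
| privacy | 0.5 | half of variants private to one population; shared variants present per population with p=0.6 |
| allele frequency | Beta(0.5, 10) where present | rare-skewed spectrum; absent is exactly 0 |
| ΔΔG mixture | N(1.5, 0.4) / N(0, 0.18) / N(−1.3, 0.35) | components clipped ≥ 0.55, within ±0.45, ≤ −0.55 so class labels never flip at the ±0.5 boundaries |
| planted modules | 8 × 20 nodes, 3× density | detectable but not saturated rewiring contrast |
| ER sets | disjoint, medians 0.235/0.223/0.197, SD 0.15 | published per-set medians; disjointness gives each gene one planted rate |
| term map | 30 level-3 terms, 3 planted at odds 5 | enough multiplicity for FDR behavior |

Planted module density works by routing a detrimental variant to a
module-internal edge with probability w = (M−1)r/(1+(M−1)r) (r the internal
edge fraction, M the multiplier), which multiplies the internal per-edge
detrimental rate by M in expectation. At high variant-to-edge ratios the
per-edge *disruption* probability saturates toward 1 and the observable
contrast shrinks; recovery tests therefore run below saturation.

What the generator does **not** emulate: linkage disequilibrium,
demography, realistic site-frequency spectra, sequence-level structure, or
any correlation between a variant's ΔΔG and its frequency. Passing recovery
tests therefore demonstrates that the pipeline's statistics detect the
structures they target at realistic effect sizes — not that real data
contain those structures.

## Problem sizes and determinism

Desk-scale defaults (400-protein graphs, 2000 variants, R ≈ 200–1000
permutations, 20–30 modules per arm) keep the full test suite and the
reproduction script in the minutes range on one CPU; all stochastic steps
take explicit integer seeds and the pipeline writes a manifest with the
config hash and seed per run.

## Known limitations

- Observed headline values from the original population-scale study
  (e.g., dataset-wide divergence 0.405, subnetwork efficiencies
  0.0117/0.0223, 1055 topology modules, 458 enriched terms) depend on
  restricted-scale real inputs and are reproduced procedurally, not
  numerically.
- One reported population percentage (54.1%) disagrees with its own
  printed counts (25,185/46,599 = 54.0%); the package reports the
  recomputed value.
- Finite-k DSD differs from the converged variant; module boundaries can
  shift with k on weakly modular graphs.
- DIAMOnD p-values are greedy ranking scores, not calibrated significance
  levels; they should not be interpreted as hypothesis tests.
- The spectral module confidence filter is size-only; no stability or
  reproducibility scoring across seeds is implemented.
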