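"""Merge two PPI edge sources into one analysis interactome.

Two curated edge lists (think of a literature-mined database and a
systematic yeast-two-hybrid screen) usually overlap only partially; the
analysis runs on their union, with per-edge provenance retained.
"""

from edgetics import Interactome, merge_interactomes

literature = Interactome()
for a, b in [("TP53", "MDM2"), ("TP53", "EP300"), ("BRCA1", "BARD1"),
             ("ALDH2", "ALDH2")]:  # a homo-oligomer self-interaction
    literature.add_edge(a, b, ["literature"])

screen = Interactome()
for a, b in [("TP53", "MDM2"), ("BRCA1", "BRIP1"), ("ALDH2", "ALDH1A1")]:
    screen.add_edge(a, b, ["screen"])

merged = merge_interactomes(literature, screen)
shared = literature.edge_keys() & screen.edge_keys()

print(f"source sizes: {literature.n_edges} and {screen.n_edges} edges")
print(f"shared edges: {len(shared)}")
print(f"merged interactome: {merged.n_nodes} proteins, {merged.n_edges} edges")
for e in merged.edges():
    print(f"  {e.a} -- {e.b}  sources={sorted(e.sources)}")
# |union| = |x| + |y| - |x∩y|: the merged count reflects deduplicated
# evidence, and doubly supported edges carry both source labels.
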