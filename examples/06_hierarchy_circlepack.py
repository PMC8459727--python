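"""Pathway hierarchy assembly and circle-pack export.

Hangs merged pathway groups below category roots with is-part-of
relations, validates the DAG (acyclic, depth <= 4, no orphans), and
exports the nested circle-pack structure coloured by GSEA results.
"""

import json

from pathconsensus import (
    MappingRecord,
    build_equivalence_groups,
    build_hierarchy,
    export_circlepack,
    simulate_database_family,
)

collections, mappings, truth = simulate_database_family(
    n_groups=4, universe_size=600, genes_per_set=25, seed=8
)
groups = build_equivalence_groups(mappings, collections)

# nest the four merged groups below two category roots
roots = {"metabolism": "Metabolism", "signaling": "Signaling"}
part_of = [
    MappingRecord(source_db=db, source_id=sid, source_name=g.group_name,
                  relation="isPartOf", target_db="category",
                  target_id=root, target_name=roots[root])
    for g, root in zip(groups, ["metabolism", "metabolism",
                                "signaling", "signaling"])
    for db, sid in g.members[:1]
]
hierarchy = build_hierarchy(mappings + part_of, groups, roots)
print("pathway nodes:", hierarchy.n_pathways,
      "| roots:", len(hierarchy.roots),
      "| max depth:", hierarchy.depth(),
      "| issues:", hierarchy.validate())

# fake enrichment results for two of the groups
results = {
    groups[0].group_id: {"p_adj": 0.004, "nes": 2.3},
    groups[2].group_id: {"p_adj": 0.30, "nes": 0.9},
}
tree = export_circlepack(hierarchy, results, method="gsea", alpha=0.05)
print(json.dumps(tree.to_dict(), indent=2)[:900], "...")
print(
    "\nNode size is merged gene-set cardinality; significant nodes carry "
    "their signed NES as color_value (red/blue in a front-end), and "
    "non-significant or untested nodes stay uncoloured (gray)."
)
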