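"""Explaining a cross-database contradiction at the gene level.

Plants signal only in the genes exclusive to one database's version of a
pathway: that database calls the pathway enriched, the others do not.
The Venn-region decomposition with fold-change annotation pinpoints the
exclusive region carrying the signal — the mechanism behind real
cross-database NES sign conflicts.
"""

import json

from pathconsensus import (
    build_equivalence_groups,
    consensus_table,
    explain_discrepancy,
    run_gsea,
    simulate_database_family,
    simulate_expression,
)
from pathconsensus.consensus import METHOD_SCORE_BASED, results_from_gsea

collections, mappings, truth = simulate_database_family(seed=55)
sets = {(c.database, s.set_id): set(s.genes) for c in collections for s in c.sets}
members = truth.equivalence_map["T001"]
db2 = ("DB2", "DB2:T001")
exclusive = sets[db2] - set().union(*(sets[m] for m in members if m != db2))
truth.add_gene_group("db2-exclusive", exclusive).plant("db2-exclusive", "up", 2.0)

universe = [f"G{i + 1:04d}" for i in range(2000)]
expr, dge = simulate_expression(universe, truth, n_per_group=20, seed=56)

results = []
for coll in collections:
    results.extend(run_gsea(expr, coll, B=500, seed=57))
results_by_db = results_from_gsea(results)

groups = build_equivalence_groups(mappings, collections)
group = next(g for g in groups if db2 in g.members)
records, summary, _ = consensus_table(groups, results_by_db,
                                      method_kind=METHOD_SCORE_BASED)
record = next(r for r in records if r.group_id == group.group_id)
print("consensus label:", record.label)
for db, call in sorted(record.per_database.items()):
    print(f"  {db}: q={call.p_adj:.3f} nes={call.nes:+.2f} "
          f"significant={call.significant}")

report = explain_discrepancy(group, results_by_db,
                             {c.database: c for c in collections}, dge=dge)
print("\ntop exclusive regions (by |mean log2FC|):")
print(json.dumps(report["ranked_exclusive_regions"], indent=2))
print(
    "\nOnly DB2's variant is significant, and the region ranked first is "
    "exactly DB2's exclusive gene block with mean log2FC near +2 — the "
    "genes that explain the disagreement."
)
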