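"""Two-group GSEA on synthetic expression with one planted pathway.

Simulates three overlapping pathway "databases", shifts every gene of one
pathway up by one standard deviation in the case group, and runs GSEA
with a phenotype-permutation null on the first database.
"""

from pathconsensus import simulate_database_family, simulate_expression, run_gsea
from pathconsensus.gsea import gsea_results_frame

collections, mappings, truth = simulate_database_family(seed=1)
truth.plant("T001", direction="up", effect=1.0)

universe = [f"G{i + 1:04d}" for i in range(2000)]
expr, dge = simulate_expression(universe, truth, n_per_group=20, seed=2)

results = run_gsea(expr, collections[0], B=500, seed=3)
df = gsea_results_frame(results).drop(columns="leading_edge")
print(df.to_string(index=False))
print(
    "\nThe planted pathway (DB1:T001) gets a positive NES and a small "
    "nominal p; the nine unperturbed pathways hover around |NES| ~ 1 with "
    "uniform p-values."
)
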