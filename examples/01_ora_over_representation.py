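"""Over-representation analysis of a query gene list against one database.

Builds a tiny gene-set collection, queries it with a list that fully
covers one pathway, and prints the exact one-sided Fisher p-values with
Benjamini-Yekutieli correction.
"""

from pathconsensus import GeneSet, GeneSetCollection, run_ora
from pathconsensus.ora import ora_results_frame

collection = GeneSetCollection(
    database="KEGG",
    sets=[
        GeneSet("CELL_CYCLE", "cell cycle", "KEGG",
                frozenset({"CDK1", "CDK2", "CCNB1", "CCNA2", "CDC20"})),
        GeneSet("APOPTOSIS", "apoptosis", "KEGG",
                frozenset({"CASP3", "CASP8", "CASP9", "BAX", "BCL2", "TP53"})),
        GeneSet("GLYCOLYSIS", "glycolysis", "KEGG",
                frozenset({"HK1", "HK2", "PFKM", "PKM", "GAPDH", "ENO1"})),
    ],
)

# query: all five cell-cycle genes plus one apoptosis gene
query = ["CDK1", "CDK2", "CCNB1", "CCNA2", "CDC20", "TP53"]
# background: every gene the collection knows about plus unannotated filler
universe = sorted(collection.all_genes()) + [f"FILLER{i}" for i in range(83)]

results = run_ora(query, collection, universe=universe)
print(ora_results_frame(results).to_string(index=False))
print(
    "\nk of K pathway genes hit by the n-gene query in a universe of N; the "
    "fully covered cell-cycle set has the smallest adjusted p."
)
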