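import numpy as np
import pytest

from pathconsensus import (
    EquivalenceGroup,
    GeneSet,
    GeneSetCollection,
    simulate_database_family,
    simulate_expression,
)


def make_collection(database, sets):
    """sets: {set_id: iterable of genes}"""
    return GeneSetCollection(
        database=database,
        sets=[
            GeneSet(set_id=sid, name=sid.lower(), database=database,
                    genes=frozenset(genes))
            for sid, genes in sets.items()
        ],
    )


@pytest.fixture
def two_db_collections():
    kegg = make_collection("KEGG", {
        "hsa1": {"TP53", "BRCA1", "MDM2"},
        "hsa2": {"AKT1", "PIK3CA", "PTEN", "MTOR"},
    })
    reactome = make_collection("Reactome", {
        "R-1": {"TP53", "BRCA1", "ATM"},
        "R-2": {"GAPDH", "ACTB", "TUBB"},
    })
    return [kegg, reactome]


@pytest.fixture
def synthetic_bundle():
    """Small database family + expression with one planted group."""
    colls, mappings, truth = simulate_database_family(
        n_groups=5, dbs_per_group=3, genes_per_set=30, universe_size=800, seed=11
    )
    truth.plant("T001", "up", 1.0)
    universe = [f"G{i + 1:03d}" for i in range(800)]
    expr, dge = simulate_expression(universe, truth, n_per_group=10, seed=12)
    return colls, mappings, truth, expr, dge


def designed_consensus_groups():
    """Ten two-database groups with designed significance patterns.

    5 significant everywhere with agreeing NES signs, 3 with mixed
    significance, 2 significant everywhere with opposing NES signs.
    Returns (groups, results_by_db).
    """
    groups = []
    results = {"KEGG": {}, "Reactome": {}}

    def add(i, p_kegg, nes_kegg, p_reac, nes_reac):
        gid = f"DC:{i:04d}"
        groups.append(EquivalenceGroup(
            group_id=gid, group_name=f"group {i}",
            members=[("KEGG", f"hsa{i}"), ("Reactome", f"R-{i}")],
            merged_genes=frozenset({f"GENE{i}A", f"GENE{i}B"}),
        ))
        results["KEGG"][f"hsa{i}"] = {"p_adj": p_kegg, "nes": nes_kegg}
        results["Reactome"][f"R-{i}"] = {"p_adj": p_reac, "nes": nes_reac}

    for i in range(1, 6):  # concordant significant
        add(i, 0.01, 2.0, 0.02, 1.5)
    for i in range(6, 9):  # mixed significance
        add(i, 0.01, 2.0, 0.40, 1.1)
    for i in range(9, 11):  # direction conflict
        add(i, 0.01, 1.9, 0.02, -1.8)
    return groups, results


@pytest.fixture
def consensus_fixture():
    return designed_consensus_groups()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
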