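import numpy as np
import pytest

from _oracles import connected_components_bruteforce
from pathconsensus import (
    GeneSet,
    GeneSetCollection,
    MappingRecord,
    ValidationError,
    build_equivalence_groups,
    build_hierarchy,
    export_circlepack,
    export_meta_collection,
    write_gmt,
    read_gmt,
)

from conftest import make_collection


def equiv(src, tgt):
    return MappingRecord(
        source_db=src[0], source_id=src[1], source_name=src[1],
        relation="equivalentTo",
        target_db=tgt[0], target_id=tgt[1], target_name=tgt[1],
    )


def part_of(src, tgt):
    return MappingRecord(
        source_db=src[0], source_id=src[1], source_name=src[1],
        relation="isPartOf",
        target_db=tgt[0], target_id=tgt[1], target_name=tgt[1],
    )


def test_transitive_closure_merges_chained_mappings():
    """A≡B and B≡C yield one group {A, B, C} with the union gene set."""
    colls = [
        make_collection("D1", {"A": {"a", "b"}}),
        make_collection("D2", {"B": {"b", "c"}}),
        make_collection("D3", {"C": {"c", "d"}}),
    ]
    maps = [equiv(("D1", "A"), ("D2", "B")), equiv(("D2", "B"), ("D3", "C"))]
    groups = build_equivalence_groups(maps, colls)
    assert len(groups) == 1
    g = groups[0]
    assert sorted(g.members) == [("D1", "A"), ("D2", "B"), ("D3", "C")]
    assert g.merged_genes == frozenset({"a", "b", "c", "d"})
    assert g.group_id.startswith("DC:")


def test_unmapped_pathway_becomes_singleton_with_original_id():
    colls = [make_collection("D1", {"A": {"a"}, "LONER": {"x", "y"}}),
             make_collection("D2", {"B": {"b"}})]
    groups = build_equivalence_groups([equiv(("D1", "A"), ("D2", "B"))], colls)
    by_id = {g.group_id: g for g in groups}
    assert "LONER" in by_id
    assert by_id["LONER"].merged_genes == frozenset({"x", "y"})
    assert by_id["LONER"].is_singleton()


def test_unknown_mapping_reference_reported_not_fatal():
    colls = [make_collection("D1", {"A": {"a"}})]
    report = []
    groups = build_equivalence_groups(
        [equiv(("D1", "A"), ("D2", "MISSING"))], colls, report=report
    )
    assert len(groups) == 1 and groups[0].group_id == "A"
    assert any("MISSING" in r for r in report)


def test_grouping_matches_bruteforce_components_on_random_graphs(rng):
    """Equivalence grouping equals connected components on random mapping
    graphs of up to 50 pathways."""
    for trial in range(30):
        n = int(rng.integers(2, 51))
        nodes = [("DB" + str(i % 4), f"P{i}") for i in range(n)]
        n_edges = int(rng.integers(0, n))
        edges = [
            tuple(sorted([nodes[int(rng.integers(n))], nodes[int(rng.integers(n))]]))
            for _ in range(n_edges)
        ]
        edges = [(a, b) for a, b in edges if a != b]
        colls_by_db = {}
        for db, pid in nodes:
            colls_by_db.setdefault(db, {})[pid] = {f"g_{pid}"}
        colls = [make_collection(db, sets) for db, sets in colls_by_db.items()]
        groups = build_equivalence_groups([equiv(a, b) for a, b in edges], colls)
        got = {frozenset(g.members) for g in groups if not g.is_singleton()}
        expected = set(connected_components_bruteforce(edges))
        assert got == expected
        # every node appears in exactly one group
        seen = [m for g in groups for m in g.members]
        assert sorted(seen) == sorted(nodes)


def test_union_conservation(synthetic_bundle):
    """gene in merged_genes iff it is in some member's set."""
    colls, mappings, truth, _, _ = synthetic_bundle
    sets = {(c.database, s.set_id): s.genes for c in colls for s in c.sets}
    for g in build_equivalence_groups(mappings, colls):
        union = set().union(*(sets[m] for m in g.members))
        assert set(g.merged_genes) == union
        assert len(g.merged_genes) >= max(len(sets[m]) for m in g.members)


def test_meta_collection_roundtrips_as_gmt(tmp_path, synthetic_bundle):
    colls, mappings, *_ = synthetic_bundle
    groups = build_equivalence_groups(mappings, colls)
    meta = export_meta_collection(groups)
    assert len(meta) == len(groups)
    write_gmt(meta, tmp_path / "meta.gmt")
    back = read_gmt(tmp_path / "meta.gmt", database=meta.database)
    assert {s.set_id: s.genes for s in back} == {s.set_id: s.genes for s in meta}


# --- hierarchy ------------------------------------------------------------


def _simple_groups():
    colls = [make_collection("D1", {"A": {"a"}, "B": {"b"}, "C": {"c"}})]
    return colls, build_equivalence_groups([], colls)


def test_cycle_is_fatal():
    _, groups = _simple_groups()
    maps = [part_of(("D1", "A"), ("D1", "B")), part_of(("D1", "B"), ("D1", "A"))]
    with pytest.raises(ValidationError, match="cycle"):
        build_hierarchy(maps, groups, {"root": "Root"})


def test_depth_beyond_four_is_flagged():
    colls = [make_collection("D1", {f"P{i}": {f"g{i}"} for i in range(4)})]
    groups = build_equivalence_groups([], colls)
    chain = [part_of(("D1", f"P{i + 1}"), ("D1", f"P{i}")) for i in range(3)]
    chain.append(part_of(("D1", "P0"), ("cat", "root")))
    h = build_hierarchy(chain, groups, {"root": "Root"})
    assert h.depth() == 5
    assert any("depth" in issue for issue in h.validate())
    with pytest.raises(ValidationError):
        build_hierarchy(chain, groups, {"root": "Root"}, strict_depth=True)


def test_eight_roots_and_orphan_detection():
    colls = [make_collection("D1", {"A": {"a"}, "ORPHAN": {"o"}})]
    groups = build_equivalence_groups([], colls)
    roots = {f"cat{i}": f"category {i}" for i in range(8)}
    h = build_hierarchy([part_of(("D1", "A"), ("x", "cat0"))], groups, roots)
    assert len(h.roots) == 8
    assert h.orphans() == ["ORPHAN"]
    assert any("ORPHAN" in issue for issue in h.validate())


def test_circlepack_duplicates_multi_parent_nodes():
    """A pathway under two parents appears once per parent in the tree."""
    colls = [make_collection("D1", {"A": {"a"}, "P1": {"p"}, "P2": {"q"}})]
    groups = build_equivalence_groups([], colls)
    maps = [
        part_of(("D1", "P1"), ("c", "root")),
        part_of(("D1", "P2"), ("c", "root")),
        part_of(("D1", "A"), ("D1", "P1")),
        part_of(("D1", "A"), ("D1", "P2")),
    ]
    h = build_hierarchy(maps, groups, {"root": "Root"})
    tree = export_circlepack(h, {}, method="ora")
    flat = []

    def walk(node):
        flat.append(node.node_id)
        for c in node.children:
            walk(c)

    walk(tree)
    assert flat.count("A") == 2
    dag_leaves = [n for n in h.graph.nodes if h.graph.in_degree(n) == 0]
    assert tree.leaf_count() >= len(dag_leaves)


def test_circlepack_color_semantics():
    colls = [make_collection("D1", {"A": {"a"}, "B": {"b"}, "C": {"c"}})]
    groups = build_equivalence_groups([], colls)
    maps = [part_of(("D1", x), ("c", "root")) for x in "ABC"]
    h = build_hierarchy(maps, groups, {"root": "Root"})
    results = {
        "A": {"p_adj": 0.20, "nes": 1.4},   # not significant -> gray
        "B": {"p_adj": 0.01, "nes": -1.8},  # significant, negative NES
    }
    tree = export_circlepack(h, results, method="gsea", alpha=0.05)
    nodes = {c.node_id: c for c in tree.children[0].children}
    assert nodes["A"].significant is False and nodes["A"].color_value is None
    assert nodes["B"].significant is True and nodes["B"].color_value == -1.8
    assert nodes["C"].significant is None  # no result at all

    ora_tree = export_circlepack(h, {"A": {"p_adj": 0.04}}, method="ora")
    assert ora_tree.children[0].children[0].significant is True


def test_circlepack_unmapped_results_get_catchall_root():
    colls = [make_collection("D1", {"A": {"a"}})]
    groups = build_equivalence_groups([], colls)
    h = build_hierarchy([part_of(("D1", "A"), ("c", "root"))], groups, {"root": "R"})
    tree = export_circlepack(h, {"GHOST": {"p_adj": 0.01}}, method="ora")
    holders = [c for c in tree.children if c.node_id == "__unmapped__"]
    assert len(holders) == 1
    assert holders[0].children[0].node_id == "GHOST"
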