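"""Equivalence layer and pathway hierarchy.

Pathways describing the same biological process in different databases are
linked by curated ``equivalentTo`` mappings.  Equivalence is taken as a
true equivalence relation, so groups are the connected components of the
mapping graph; each component is collapsed into one meta-pathway with a
fresh unique identifier and the union of its members' gene sets.  A
second relation, ``isPartOf``, nests pathways below eight top-level
categories (metabolism, immune, signaling, ...), giving a directed
acyclic hierarchy whose published form has maximum depth 4.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import ValidationError
from .io_formats import (
    RELATION_EQUIVALENT,
    RELATION_PART_OF,
    GeneSet,
    GeneSetCollection,
    MappingRecord,
)

logger = logging.getLogger(__name__)

#: collection label of the merged meta-database
META_DATABASE = "MERGED"

MAX_DEPTH = 4


@dataclass
class EquivalenceGroup:
    """A merged meta-pathway: one node per class of equivalent pathways."""

    group_id: str
    group_name: str
    members: list[tuple[str, str]]  # (database, set_id)
    merged_genes: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"group {self.group_id!r} has no members")

    @property
    def databases(self) -> list[str]:
        return sorted({db for db, _ in self.members})

    def is_singleton(self) -> bool:
        return len(self.members) == 1


@dataclass
class PathwayHierarchy:
    """DAG over category roots and (collapsed) pathway nodes.

    Edges point child -> parent.  Node attributes: ``kind`` in
    {"category", "pathway"}, ``name``, and for pathway nodes ``size``
    (merged gene-set cardinality).
    """

    graph: nx.DiGraph
    roots: list[str]

    @property
    def n_pathways(self) -> int:
        return sum(1 for n, d in self.graph.nodes(data=True) if d["kind"] == "pathway")

    def depth(self) -> int:
        """Longest root-to-leaf path length counted in nodes (root = 1)."""
        rev = self.graph.reverse(copy=False)  # parent -> child
        memo: dict[str, int] = {}

        def down(node: str) -> int:
            if node in memo:
                return memo[node]
            children = list(rev.successors(node))
            memo[node] = 1 + (max(down(c) for c in children) if children else 0)
            return memo[node]

        return max((down(r) for r in self.roots), default=0)

    def orphans(self) -> list[str]:
        """Nodes with no path to any root."""
        reachable: set[str] = set(self.roots)
        rev = self.graph.reverse(copy=False)
        for r in self.roots:
            reachable |= nx.descendants(rev, r)
        return sorted(set(self.graph.nodes) - reachable)

    def validate(self) -> list[str]:
        """Return a list of validation issues; cycles raise immediately."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValidationError(
                "hierarchy contains a cycle: "
                + " -> ".join(str(u) for u, _ in cycle)
                + f" -> {cycle[0][0]}"
            )
        issues: list[str] = []
        d = self.depth()
        if d > MAX_DEPTH:
            issues.append(f"depth {d} exceeds maximum {MAX_DEPTH}")
        for node in self.orphans():
            issues.append(f"orphan node {node!r} (no path to a root)")
        return issues


@dataclass
class CirclePackNode:
    """Nested node of the circle-pack export (a tree, JSON-serializable)."""

    node_id: str
    name: str
    size: int
    significant: bool | None = None
    color_value: float | None = None
    children: list["CirclePackNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "id": self.node_id,
            "name": self.name,
            "size": self.size,
            "significant": self.significant,
            "color_value": self.color_value,
            "children": [c.to_dict() for c in self.children],
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def leaf_count(self) -> int:
        if not self.children:
            return 1
        return sum(c.leaf_count() for c in self.children)


# ---------------------------------------------------------------------------
# equivalence groups
# ---------------------------------------------------------------------------


def build_equivalence_groups(
    mappings: list[MappingRecord],
    collections: list[GeneSetCollection],
    report: list[str] | None = None,
) -> list[EquivalenceGroup]:
    """Collapse ``equivalentTo`` mappings into merged meta-pathways.

    Groups are connected components of the undirected graph whose edges
    are the equivalentTo records (transitive closure across databases).
    Pathways never mentioned in an equivalentTo record become singleton
    groups that keep their original identifier.  Mapping rows referencing
    pathways absent from the supplied collections are excluded with a
    warning collected into ``report``.
    """
    known: dict[tuple[str, str], GeneSet] = {}
    for coll in collections:
        for gs in coll.sets:
            known[(coll.database, gs.set_id)] = gs

    g = nx.Graph()
    for rec in mappings:
        if rec.relation != RELATION_EQUIVALENT:
            continue
        src = (rec.source_db, rec.source_id)
        tgt = (rec.target_db, rec.target_id)
        dropped = [p for p in (src, tgt) if p not in known]
        if dropped:
            for db, pid in dropped:
                msg = f"equivalentTo record references unknown pathway {db}:{pid}"
                logger.warning(msg)
                if report is not None:
                    report.append(msg)
            continue
        g.add_edge(src, tgt)

    groups: list[EquivalenceGroup] = []
    grouped: set[tuple[str, str]] = set()
    # stable ordering: components sorted by their smallest member
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    width = max(4, len(str(len(components))))
    for i, comp in enumerate(components, start=1):
        grouped |= set(comp)
        group_id = f"DC:{i:0{width}d}"
        name = known[comp[0]].name
        merged = frozenset().union(*(known[m].genes for m in comp))
        groups.append(
            EquivalenceGroup(
                group_id=group_id, group_name=name, members=list(comp),
                merged_genes=merged,
            )
        )
    for (db, set_id), gs in sorted(known.items()):
        if (db, set_id) in grouped:
            continue
        groups.append(
            EquivalenceGroup(
                group_id=set_id,
                group_name=gs.name,
                members=[(db, set_id)],
                merged_genes=gs.genes,
            )
        )
    return groups


def export_meta_collection(
    groups: list[EquivalenceGroup], database: str = META_DATABASE
) -> GeneSetCollection:
    """One merged gene set per equivalence group, writable as GMT."""
    sets = [
        GeneSet(
            set_id=grp.group_id,
            name=grp.group_name,
            database=database,
            genes=grp.merged_genes,
        )
        for grp in groups
    ]
    return GeneSetCollection(database=database, sets=sets)


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


def build_hierarchy(
    mappings: list[MappingRecord],
    groups: list[EquivalenceGroup],
    category_roots: dict[str, str],
    strict_depth: bool = False,
) -> PathwayHierarchy:
    """Assemble the is-part-of DAG over collapsed nodes.

    ``category_roots`` maps root category id -> display name.  isPartOf
    edges whose endpoints are member pathways are re-attached to the
    member's equivalence-group node.  Cycles are fatal; depth beyond the
    published maximum and orphans are validation issues (fatal only when
    ``strict_depth``).
    """
    member_to_group: dict[tuple[str, str], EquivalenceGroup] = {}
    by_id: dict[str, EquivalenceGroup] = {}
    for grp in groups:
        by_id[grp.group_id] = grp
        for m in grp.members:
            member_to_group[m] = grp

    g = nx.DiGraph()
    for cid, cname in category_roots.items():
        g.add_node(cid, kind="category", name=cname)
    for grp in groups:
        g.add_node(
            grp.group_id, kind="pathway", name=grp.group_name,
            size=len(grp.merged_genes),
        )

    def resolve(db: str, pid: str) -> str | None:
        if pid in category_roots:
            return pid
        grp = member_to_group.get((db, pid))
        if grp is not None:
            return grp.group_id
        if pid in by_id:
            return pid
        return None

    for rec in mappings:
        if rec.relation != RELATION_PART_OF:
            continue
        child = resolve(rec.source_db, rec.source_id)
        parent = resolve(rec.target_db, rec.target_id)
        if child is None or parent is None:
            logger.warning(
                "isPartOf record references unknown node %s:%s -> %s:%s",
                rec.source_db, rec.source_id, rec.target_db, rec.target_id,
            )
            continue
        if child != parent:
            g.add_edge(child, parent)  # child -> parent

    hierarchy = PathwayHierarchy(graph=g, roots=sorted(category_roots))
    issues = hierarchy.validate()  # raises on cycles
    for issue in issues:
        logger.warning("hierarchy validation: %s", issue)
    if strict_depth and any("depth" in i for i in issues):
        raise ValidationError("; ".join(i for i in issues if "depth" in i))
    return hierarchy


# ---------------------------------------------------------------------------
# circle-pack export
# ---------------------------------------------------------------------------


def export_circlepack(
    hierarchy: PathwayHierarchy,
    results: dict[str, dict],
    method: str,
    alpha: float = 0.05,
    root_name: str = "pathways",
) -> CirclePackNode:
    """Export the hierarchy as a nested tree with enrichment colouring.

    ``results`` maps node id -> record with key ``p_adj`` and, for
    score-based methods, ``nes``.  Semantics follow the visual contract:
    score-based ("gsea") nodes are significant iff adjusted p < alpha and
    carry the signed NES as ``color_value``; "ora" nodes carry only the
    significance flag.  A node with several parents is duplicated under
    each (circle packing lays out a tree, not a DAG).  Results for nodes
    missing from the hierarchy are attached under an "unmapped" root.
    """
    method = method.lower()
    if method not in {"ora", "gsea"}:
        raise ValidationError(f"unknown method {method!r}; expected 'ora' or 'gsea'")

    rev = hierarchy.graph.reverse(copy=False)  # parent -> child

    def annotate(node_id: str) -> CirclePackNode:
        data = hierarchy.graph.nodes[node_id]
        size = int(data.get("size", 0))
        node = CirclePackNode(
            node_id=node_id, name=data.get("name", node_id), size=size
        )
        rec = results.get(node_id)
        if rec is not None:
            p_adj = float(rec["p_adj"])
            node.significant = p_adj < alpha
            if method == "gsea":
                node.color_value = float(rec["nes"]) if node.significant else None
        node.children = [annotate(c) for c in sorted(rev.successors(node_id))]
        return node

    root = CirclePackNode(node_id="__root__", name=root_name, size=0)
    root.children = [annotate(r) for r in hierarchy.roots]

    unmapped = sorted(set(results) - set(hierarchy.graph.nodes))
    if unmapped:
        logger.warning(
            "%d result node(s) absent from hierarchy; attached under 'unmapped'",
            len(unmapped),
        )
        holder = CirclePackNode(node_id="__unmapped__", name="unmapped", size=0)
        for node_id in unmapped:
            rec = results[node_id]
            p_adj = float(rec["p_adj"])
            child = CirclePackNode(
                node_id=node_id, name=node_id, size=int(rec.get("size", 0) or 0),
                significant=p_adj < alpha,
            )
            if method == "gsea" and child.significant:
                child.color_value = float(rec["nes"])
            holder.children.append(child)
        root.children.append(holder)
    return root
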