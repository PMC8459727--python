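"""Gene-level decomposition of equivalent gene sets.

When databases disagree about a pathway, the disagreement usually lives
in the genes one database includes and another leaves out.  This module
partitions the union of 2-4 equivalent gene sets into Venn regions (one
region per membership signature), annotates each region with the
distribution of log2 fold changes, and ranks exclusive regions by how
strongly their genes move — the pattern behind classic cross-database
sign conflicts, where the genes unique to one database's version of a
pathway carry a directional signal the shared core lacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import DGETable

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 21


@dataclass
class RegionSummary:
    """Fold-change summary for one Venn region."""

    n: int
    mean_log2fc: float | None
    counts: list[int]
    missing: int  # region genes absent from the DGE table


@dataclass
class RegionDecomposition:
    """Exact partition of a union of gene sets by membership signature.

    ``sets``: ordered (database, set_id) labels.  ``regions`` maps a
    signature string (one character per set, '1' = member) to the sorted
    genes carrying exactly that membership pattern; empty regions are
    omitted.  ``bin_edges``/``summaries`` are filled by
    :func:`annotate_fold_changes`.
    """

    sets: list[tuple[str, str]]
    regions: dict[str, list[str]]
    bin_edges: list[float] = field(default_factory=list)
    summaries: dict[str, RegionSummary] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.sets)

    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= set(genes)
        return out

    def exclusive_signatures(self) -> list[str]:
        return [sig for sig in self.regions if sig.count("1") == 1]

    def to_dict(self) -> dict:
        return {
            "sets": [list(s) for s in self.sets],
            "bin_edges": self.bin_edges,
            "regions": [
                {
                    "signature": sig,
                    "genes": genes,
                    "n": len(genes),
                    **(
                        {
                            "mean_log2fc": self.summaries[sig].mean_log2fc,
                            "counts": self.summaries[sig].counts,
                            "missing": self.summaries[sig].missing,
                        }
                        if sig in self.summaries
                        else {}
                    ),
                }
                for sig, genes in sorted(self.regions.items())
            ],
        }


def venn_decompose(named_sets: list[tuple[tuple[str, str], set]]) -> RegionDecomposition:
    """Partition the union of 2-4 named gene sets into Venn regions.

    ``named_sets``: ordered ((database, set_id), genes) pairs.  Signature
    position i refers to the i-th set.  Deterministic: genes sorted
    within each region.
    """
    k = len(named_sets)
    if not 2 <= k <= 4:
        raise ValidationError(
            f"Venn decomposition supports 2-4 sets, got {k}; "
            "use pairwise overlap tables for larger families"
        )
    for label, genes in named_sets:
        if not genes:
            raise ValidationError(f"gene set {label} is empty")
    regions: dict[str, list[str]] = {}
    union: set[str] = set()
    for _, genes in named_sets:
        union |= set(genes)
    for gene in union:
        sig = "".join("1" if gene in genes else "0" for _, genes in named_sets)
        regions.setdefault(sig, []).append(gene)
    return RegionDecomposition(
        sets=[label for label, _ in named_sets],
        regions={sig: sorted(genes) for sig, genes in regions.items()},
    )


def default_bin_edges(values, n_bins: int = DEFAULT_N_BINS) -> list[float]:
    """Equal-width bins spanning the observed range symmetrized about 0."""
    arr = np.asarray(list(values), dtype=float)
    m = float(np.max(np.abs(arr))) if arr.size else 1.0
    if m == 0.0:
        m = 1.0
    return list(np.linspace(-m, m, n_bins + 1))


def annotate_fold_changes(
    decomp: RegionDecomposition,
    dge: DGETable,
    bins: list[float] | None = None,
    max_padj: float | None = None,
) -> RegionDecomposition:
    """Attach per-region log2 fold-change summaries.

    Region genes found in the DGE table contribute to the histogram and
    mean; genes absent from it are counted under ``missing``.  Summaries
    are additive across regions: summing per-bin counts over all regions
    reproduces the histogram of the union.  ``max_padj`` optionally
    restricts the annotation to genes below an adjusted-p cutoff.
    """
    fc = dge.log2fc()
    if max_padj is not None:
        padj = dge.padj()
        fc = {g: v for g, v in fc.items() if padj[g] <= max_padj}
    union_fc = [fc[g] for g in decomp.union() if g in fc]
    if not union_fc:
        logger.warning("no region gene found in the DGE table; summaries empty")
    if bins is None:
        bins = default_bin_edges(union_fc if union_fc else [1.0])
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing, length >= 2")

    decomp.bin_edges = [float(e) for e in edges]
    decomp.summaries = {}
    for sig, genes in decomp.regions.items():
        vals = np.array([fc[g] for g in genes if g in fc], dtype=float)
        missing = len(genes) - vals.size
        counts, _ = np.histogram(vals, bins=edges)
        decomp.summaries[sig] = RegionSummary(
            n=len(genes),
            mean_log2fc=float(vals.mean()) if vals.size else None,
            counts=[int(c) for c in counts],
            missing=missing,
        )
    return decomp


def explain_discrepancy(
    group,
    results_by_db: dict[str, dict[str, dict]],
    collections_by_db: dict,
    dge: DGETable | None = None,
    bins: list[float] | None = None,
) -> dict:
    """Structured gene-level report for one equivalence group.

    Pairs every exclusive Venn region (genes unique to one database's
    gene set) with its fold-change summary and the member databases'
    enrichment statistics, ordered by |mean log2fc| of the exclusive
    regions (strongest directional signal first).  Without a DGE table
    the report is limited to membership counts.
    """
    members = [
        m for m in group.members
        if m[1] in {s.set_id for s in collections_by_db[m[0]].sets}
    ] if collections_by_db else list(group.members)
    if len(members) < 2:
        raise ValidationError(
            f"group {group.group_id} needs >= 2 members with gene sets for a "
            "gene-level comparison"
        )
    named_sets = [
        ((db, set_id), set(collections_by_db[db][set_id].genes))
        for db, set_id in members
    ]
    decomp = venn_decompose(named_sets)

    stats = {}
    for db, set_id in members:
        rec = results_by_db.get(db, {}).get(set_id)
        if rec is not None:
            stats[db] = {"p_adj": rec["p_adj"], "nes": rec.get("nes")}

    report: dict = {
        "group_id": group.group_id,
        "group_name": group.group_name,
        "sets": [list(m) for m in members],
        "member_statistics": stats,
        "full_overlap": len(decomp.regions) == 1,
    }
    if dge is None:
        report["regions"] = [
            {"signature": sig, "n": len(genes), "genes": genes}
            for sig, genes in sorted(decomp.regions.items())
        ]
        report["ranked_exclusive_regions"] = []
        return report

    annotate_fold_changes(decomp, dge, bins=bins)
    report["bin_edges"] = decomp.bin_edges
    report["regions"] = decomp.to_dict()["regions"]
    exclusive = []
    for sig in decomp.exclusive_signatures():
        summ = decomp.summaries[sig]
        idx = sig.index("1")
        exclusive.append(
            {
                "signature": sig,
                "exclusive_to": list(decomp.sets[idx]),
                "n": summ.n,
                "mean_log2fc": summ.mean_log2fc,
                "missing": summ.missing,
            }
        )
    exclusive.sort(
        key=lambda r: -(abs(r["mean_log2fc"]) if r["mean_log2fc"] is not None else -1.0)
    )
    report["ranked_exclusive_regions"] = exclusive
    return report
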