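"""Cross-database consensus of enrichment results.

Equivalent pathways (one equivalence group per biological pathway) are
looked up in every selected database's result table and the group is
classified:

* ``concordant_significant``    — significant in every database it appears
  in (and, for score-based methods, with agreeing NES signs);
* ``concordant_nonsignificant`` — significant in none;
* ``contradictory_significance``— significant in some databases but not
  others;
* ``contradictory_direction``   — at least two significant members whose
  NES signs disagree (score-based methods only; takes precedence over
  the significance-based labels);
* ``single_database``           — the pathway exists in only one selected
  database, so no cross-database comparison is possible.

Comparisons are made only among databases in which the pathway exists and
for which results were supplied: absence is never treated as
non-significance.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .errors import ValidationError
from .pathway_map import EquivalenceGroup

logger = logging.getLogger(__name__)

LABEL_CONCORDANT_SIG = "concordant_significant"
LABEL_CONCORDANT_NONSIG = "concordant_nonsignificant"
LABEL_CONTRA_SIG = "contradictory_significance"
LABEL_CONTRA_DIR = "contradictory_direction"
LABEL_SINGLE = "single_database"

LABELS = (
    LABEL_CONCORDANT_SIG,
    LABEL_CONCORDANT_NONSIG,
    LABEL_CONTRA_SIG,
    LABEL_CONTRA_DIR,
    LABEL_SINGLE,
)

METHOD_ORA_LIKE = "ORA_like"
METHOD_SCORE_BASED = "score_based"


@dataclass(frozen=True)
class DatabaseCall:
    """One database's view of one pathway."""

    present: bool
    significant: bool | None = None
    direction: str = "n/a"  # "+", "-" or "n/a"
    p_adj: float | None = None
    nes: float | None = None


@dataclass
class ConsensusRecord:
    """Consensus classification of one equivalence group."""

    group_id: str
    group_name: str
    per_database: dict[str, DatabaseCall]
    label: str
    methods_covered: list[str] = field(default_factory=list)

    @property
    def databases(self) -> list[str]:
        return sorted(self.per_database)


@dataclass
class ImportedResultTable:
    """Externally computed enrichment results for upload-style ingestion.

    ``rows``: (set_id, database, p_adj, nes-or-None).  ``method_kind``
    declares how the rows should be classified downstream (topology-based
    uploads pass ``score_based`` when they carry a signed score).
    """

    method: str
    method_kind: str
    rows: list[tuple[str, str, float, float | None]]

    def __post_init__(self):
        if self.method_kind not in (METHOD_ORA_LIKE, METHOD_SCORE_BASED):
            raise ValidationError(
                f"method_kind must be {METHOD_ORA_LIKE!r} or {METHOD_SCORE_BASED!r}"
            )


# results_by_db: {database: {set_id: {"p_adj": float, "nes": float | None}}}


def results_from_ora(results) -> dict[str, dict[str, dict]]:
    """Index ORA results as {database: {set_id: record}}."""
    out: dict[str, dict[str, dict]] = {}
    for r in results:
        out.setdefault(r.database, {})[r.set_id] = {"p_adj": r.p_adj, "nes": None}
    return out


def results_from_gsea(results) -> dict[str, dict[str, dict]]:
    """Index GSEA results; the FDR q plays the adjusted statistic."""
    out: dict[str, dict[str, dict]] = {}
    for r in results:
        out.setdefault(r.database, {})[r.set_id] = {"p_adj": r.q_fdr, "nes": r.nes}
    return out


def classify_group(
    group: EquivalenceGroup,
    results_by_db: dict[str, dict[str, dict]],
    alpha: float = 0.05,
    method_kind: str = METHOD_ORA_LIKE,
) -> ConsensusRecord | None:
    """Classify one equivalence group; None when no database has a result."""
    if method_kind not in (METHOD_ORA_LIKE, METHOD_SCORE_BASED):
        raise ValidationError(f"unknown method_kind {method_kind!r}")
    per_db: dict[str, DatabaseCall] = {}
    for db, set_id in group.members:
        rec = results_by_db.get(db, {}).get(set_id)
        if rec is None:
            continue
        p_adj = float(rec["p_adj"])
        nes = rec.get("nes")
        nes = None if nes is None else float(nes)
        sig = p_adj < alpha
        if method_kind == METHOD_SCORE_BASED and nes is not None and nes != 0:
            direction = "+" if nes > 0 else "-"
        else:
            direction = "n/a"
        per_db[db] = DatabaseCall(
            present=True, significant=sig, direction=direction,
            p_adj=p_adj, nes=nes,
        )
    if not per_db:
        logger.info("group %s has no results in any database; excluded", group.group_id)
        return None

    if len(per_db) == 1:
        label = LABEL_SINGLE
    else:
        sig_calls = [c for c in per_db.values() if c.significant]
        directions = {c.direction for c in sig_calls if c.direction != "n/a"}
        if method_kind == METHOD_SCORE_BASED and len(directions) > 1:
            label = LABEL_CONTRA_DIR
        elif 0 < len(sig_calls) < len(per_db):
            label = LABEL_CONTRA_SIG
        elif len(sig_calls) == len(per_db):
            label = LABEL_CONCORDANT_SIG
        else:
            label = LABEL_CONCORDANT_NONSIG
    return ConsensusRecord(
        group_id=group.group_id,
        group_name=group.group_name,
        per_database=per_db,
        label=label,
    )


def consensus_table(
    groups: list[EquivalenceGroup],
    results_by_db: dict[str, dict[str, dict]],
    alpha: float = 0.05,
    method_kind: str = METHOD_ORA_LIKE,
) -> tuple[list[ConsensusRecord], dict[str, int], list[ConsensusRecord]]:
    """Classify every group with results.

    Returns (multi-database records, summary counts per label, singleton
    records).  Result rows whose set_id is claimed by no group are logged
    via :func:`unresolved_results`, which callers should run beforehand.
    """
    records: list[ConsensusRecord] = []
    singles: list[ConsensusRecord] = []
    for group in groups:
        rec = classify_group(group, results_by_db, alpha=alpha, method_kind=method_kind)
        if rec is None:
            continue
        (singles if rec.label == LABEL_SINGLE else records).append(rec)
    summary = Counter(r.label for r in records)
    return records, dict(summary), singles


def unresolved_results(
    groups: list[EquivalenceGroup], results_by_db: dict[str, dict[str, dict]]
) -> list[tuple[str, str]]:
    """(database, set_id) result rows that no group member claims."""
    claimed = {m for g in groups for m in g.members}
    out = [
        (db, set_id)
        for db, table in results_by_db.items()
        for set_id in table
        if (db, set_id) not in claimed
    ]
    for db, set_id in out:
        logger.warning("result row %s:%s matches no known pathway", db, set_id)
    return sorted(out)


def compare_methods(
    records_a: list[ConsensusRecord], records_b: list[ConsensusRecord]
) -> dict:
    """Cross-method agreement summary over shared equivalence groups.

    A group counts as "concordant" under a method when its label is
    ``concordant_significant``.  Returns counts of groups concordant in
    both methods, in exactly one, and in neither, plus per-group
    side-by-side labels.
    """
    by_a = {r.group_id: r for r in records_a}
    by_b = {r.group_id: r for r in records_b}
    shared = sorted(set(by_a) & set(by_b))
    if not shared and (by_a or by_b):
        logger.warning("methods share no equivalence groups; comparison is empty")
    both = only_a = only_b = neither = 0
    side_by_side = []
    for gid in shared:
        ca = by_a[gid].label == LABEL_CONCORDANT_SIG
        cb = by_b[gid].label == LABEL_CONCORDANT_SIG
        if ca and cb:
            both += 1
        elif ca:
            only_a += 1
        elif cb:
            only_b += 1
        else:
            neither += 1
        side_by_side.append(
            {"group_id": gid, "label_a": by_a[gid].label, "label_b": by_b[gid].label}
        )
    return {
        "shared_groups": len(shared),
        "concordant_both": both,
        "concordant_only_a": only_a,
        "concordant_only_b": only_b,
        "concordant_neither": neither,
        "per_group": side_by_side,
    }


def import_results(
    table: ImportedResultTable, groups: list[EquivalenceGroup]
) -> tuple[dict[str, dict[str, dict]], list[tuple[str, str]]]:
    """Attach uploaded result rows to equivalence groups.

    Rows resolve through their (database, set_id) pair; unmatched rows are
    returned separately, never silently dropped.  Duplicate (database,
    set_id) rows are an error.
    """
    claimed = {m for g in groups for m in g.members}
    seen: set[tuple[str, str]] = set()
    results_by_db: dict[str, dict[str, dict]] = {}
    unresolved: list[tuple[str, str]] = []
    for set_id, db, p_adj, nes in table.rows:
        key = (db, set_id)
        if key in seen:
            raise ValidationError(f"duplicate result row for pathway {db}:{set_id}")
        seen.add(key)
        if key not in claimed:
            unresolved.append(key)
            continue
        results_by_db.setdefault(db, {})[set_id] = {
            "p_adj": float(p_adj),
            "nes": None if nes is None else float(nes),
        }
    for db, set_id in unresolved:
        logger.warning("uploaded row %s:%s matches no known pathway", db, set_id)
    return results_by_db, sorted(unresolved)


def summary_frame(records: list[ConsensusRecord]):
    """Flat pandas view of consensus records (one row per group)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"group_id": r.group_id, "name": r.group_name, "label": r.label}
        for db, call in sorted(r.per_database.items()):
            row[f"{db}:p_adj"] = call.p_adj
            row[f"{db}:nes"] = call.nes
        rows.append(row)
    return pd.DataFrame(rows)
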