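"""Synthetic data with known ground truth.

Two generators make the whole pipeline testable without downloads:

* :func:`simulate_database_family` builds several artificial "databases"
  whose gene sets overlap the way real pathway databases do — each
  biological pathway is realized once per database as a variant sharing a
  common core, with pairwise Jaccard similarity controlled exactly — and
  emits the matching pairwise ``equivalentTo`` mapping records.
* :func:`simulate_expression` draws a two-group log2-scale expression
  matrix (Gaussian around a common baseline) and shifts the planted
  pathways' genes in one group by a stated effect size, in units of the
  within-group standard deviation.  A companion differential-expression
  table (Welch t-test + Benjamini-Hochberg) is produced as ground-truth
  support for the gene-level annotations; it is a fixture convenience,
  not a count-model analysis.

All randomness flows through one seeded generator; the same seed yields
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import (
    RELATION_EQUIVALENT,
    DGETable,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    MappingRecord,
)

DEFAULT_UNIVERSE = 2000
DEFAULT_GROUPS = 10
DEFAULT_DBS_PER_GROUP = 3
DEFAULT_SET_SIZE = 50
DEFAULT_JACCARD = (0.5, 0.8)
DEFAULT_EFFECT = 1.0
DEFAULT_N_PER_GROUP = 20
DEFAULT_BASELINE_SD = 1.0
DEFAULT_BASELINE_MEAN = 6.0  # log2 expression baseline


@dataclass
class SyntheticTruth:
    """Ground truth the generators commit to."""

    equivalence_map: dict[str, list[tuple[str, str]]]  # truth group -> members
    group_genes: dict[str, list[str]]  # truth group -> union genes
    planted_sets: list[tuple[str, str, float]] = field(default_factory=list)
    # (truth group id, direction "up"/"down", effect in sd units)
    seed: int | None = None

    def add_gene_group(self, group_id: str, genes) -> "SyntheticTruth":
        """Register an ad-hoc gene group (e.g. one database's exclusive
        genes) so signal can be planted below whole-pathway resolution."""
        if group_id in self.group_genes:
            raise ValidationError(f"group {group_id!r} already defined")
        self.group_genes[group_id] = sorted(set(genes))
        return self

    def plant(self, group_id: str, direction: str = "up", effect: float = DEFAULT_EFFECT):
        if group_id not in self.group_genes:
            raise ValidationError(f"unknown truth group {group_id!r}")
        if direction not in ("up", "down"):
            raise ValidationError("direction must be 'up' or 'down'")
        if effect <= 0:
            raise ValidationError("effect must be positive")
        self.planted_sets.append((group_id, direction, float(effect)))
        return self

    def planted_genes(self) -> dict[str, float]:
        """gene -> signed effect (sd units) over all planted groups."""
        out: dict[str, float] = {}
        for gid, direction, effect in self.planted_sets:
            signed = effect if direction == "up" else -effect
            for g in self.group_genes[gid]:
                out[g] = signed
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "equivalence_map": {
                    k: [list(m) for m in v] for k, v in self.equivalence_map.items()
                },
                "group_genes": self.group_genes,
                "planted_sets": [list(p) for p in self.planted_sets],
            },
            indent=2,
        )


def _core_size_bounds(set_size: int, jaccard_range) -> tuple[int, int]:
    """Feasible shared-core sizes for two size-s sets at the target Jaccard.

    Two variant sets of size s sharing a core of c genes (the rest
    exclusive) have Jaccard c / (2s - c), increasing in c.
    """
    lo, hi = jaccard_range
    if not (0 < lo <= hi <= 1):
        raise ValidationError("jaccard_range must satisfy 0 < lo <= hi <= 1")
    s = set_size
    feasible = [c for c in range(1, s + 1) if lo <= c / (2 * s - c) <= hi]
    if not feasible:
        attainable = sorted({round(c / (2 * s - c), 4) for c in range(1, s + 1)})
        raise ValidationError(
            f"no integer core size gives Jaccard in [{lo}, {hi}] for sets of "
            f"size {s}; attainable values range {attainable[0]}..{attainable[-1]}"
        )
    return feasible[0], feasible[-1]


def simulate_database_family(
    n_groups: int = DEFAULT_GROUPS,
    dbs_per_group: int = DEFAULT_DBS_PER_GROUP,
    jaccard_range=DEFAULT_JACCARD,
    genes_per_set: int = DEFAULT_SET_SIZE,
    universe_size: int = DEFAULT_UNIVERSE,
    seed: int | None = None,
) -> tuple[list[GeneSetCollection], list[MappingRecord], SyntheticTruth]:
    """Generate overlapping gene-set collections with known equivalences.

    Every truth group appears once per database as a variant set of
    ``genes_per_set`` genes: a shared core plus per-database exclusive
    genes, sized so every pairwise Jaccard falls inside
    ``jaccard_range``.  Groups draw disjoint gene pools from the
    universe, so planted expression signal stays confined to its group.
    """
    rng = np.random.default_rng(seed)
    c_lo, c_hi = _core_size_bounds(genes_per_set, jaccard_range)
    # worst case pool per group: smallest core, most exclusive genes
    worst = c_lo + dbs_per_group * (genes_per_set - c_lo)
    if n_groups * worst > universe_size:
        raise ValidationError(
            f"universe of {universe_size} genes cannot host {n_groups} disjoint "
            f"groups of up to {worst} genes; need >= {n_groups * worst}"
        )
    width = len(str(universe_size))
    universe = [f"G{i + 1:0{width}d}" for i in range(universe_size)]
    perm = rng.permutation(universe_size)

    db_names = [f"DB{i + 1}" for i in range(dbs_per_group)]
    collections = {db: [] for db in db_names}
    mappings: list[MappingRecord] = []
    equivalence_map: dict[str, list[tuple[str, str]]] = {}
    group_genes: dict[str, list[str]] = {}

    cursor = 0
    for g in range(n_groups):
        core_size = int(rng.integers(c_lo, c_hi + 1))
        n_excl = genes_per_set - core_size
        need = core_size + dbs_per_group * n_excl
        pool = [universe[perm[cursor + j]] for j in range(need)]
        cursor += need
        core = pool[:core_size]
        gid = f"T{g + 1:03d}"
        members: list[tuple[str, str]] = []
        union: set[str] = set(core)
        for d, db in enumerate(db_names):
            excl = pool[core_size + d * n_excl : core_size + (d + 1) * n_excl]
            genes = frozenset(core) | frozenset(excl)
            set_id = f"{db}:{gid}"
            collections[db].append(
                GeneSet(set_id=set_id, name=f"synthetic pathway {gid}",
                        database=db, genes=genes)
            )
            members.append((db, set_id))
            union |= set(genes)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                (db_i, id_i), (db_j, id_j) = members[i], members[j]
                mappings.append(
                    MappingRecord(
                        source_db=db_i, source_id=id_i,
                        source_name=f"synthetic pathway {gid}",
                        relation=RELATION_EQUIVALENT,
                        target_db=db_j, target_id=id_j,
                        target_name=f"synthetic pathway {gid}",
                    )
                )
        equivalence_map[gid] = members
        group_genes[gid] = sorted(union)

    truth = SyntheticTruth(
        equivalence_map=equivalence_map,
        group_genes=group_genes,
        seed=seed if seed is None else int(seed),
    )
    out = [GeneSetCollection(database=db, sets=sets) for db, sets in collections.items()]
    return out, mappings, truth


def simulate_expression(
    universe,
    truth: SyntheticTruth,
    n_per_group: int = DEFAULT_N_PER_GROUP,
    baseline_sd: float = DEFAULT_BASELINE_SD,
    baseline_mean: float = DEFAULT_BASELINE_MEAN,
    seed: int | None = None,
) -> tuple[ExpressionDataset, DGETable]:
    """Two-group log2-scale expression with the truth's planted signal.

    Null genes are Normal(baseline_mean, baseline_sd) in both groups;
    genes of a planted group are shifted by ``±effect * baseline_sd`` in
    class A ("caseA").  Because values are already on the log2 scale, the
    expected log2 fold change of a planted gene equals
    ``±effect * baseline_sd`` directly.  The companion DGE table holds
    the observed per-gene mean difference (log2fc) and Welch-t p-values
    with Benjamini-Hochberg adjustment.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    universe = list(universe)
    shifts = truth.planted_genes()
    outside = [g for g in shifts if g not in set(universe)]
    if outside:
        raise ValidationError(
            f"planted genes absent from the universe: {outside[:5]}"
        )
    rng = np.random.default_rng(seed)
    n_genes = len(universe)
    a_cols = [f"A{i + 1}" for i in range(n_per_group)]
    b_cols = [f"B{i + 1}" for i in range(n_per_group)]
    x = rng.normal(baseline_mean, baseline_sd, size=(n_genes, 2 * n_per_group))
    shift = np.array([shifts.get(g, 0.0) for g in universe]) * baseline_sd
    x[:, : n_per_group] += shift[:, None]

    values = pd.DataFrame(x, index=universe, columns=a_cols + b_cols)
    labels = {**{s: "caseA" for s in a_cols}, **{s: "caseB" for s in b_cols}}
    expr = ExpressionDataset(values=values, labels=labels)

    xa, xb = x[:, :n_per_group], x[:, n_per_group:]
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    _, pvals = sps.ttest_ind(xa, xb, axis=1, equal_var=False)
    padj = multipletests(pvals, method="fdr_bh")[1]
    dge = DGETable(
        table=pd.DataFrame({"gene": universe, "log2fc": log2fc, "padj": padj})
    )
    return expr, dge


def write_fixture_bundle(out_dir, collections, mappings, truth, expr=None, dge=None):
    """Write a complete plain-text fixture bundle (GMTs, mapping TSV,
    expression + design TSVs, DGE TSV, truth JSON)."""
    import os

    from .io_formats import write_gmt, write_mapping_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for coll in collections:
        p = os.path.join(out_dir, f"{coll.database}.gmt")
        write_gmt(coll, p)
        paths[coll.database] = p
    mp = os.path.join(out_dir, "mappings.tsv")
    write_mapping_table(mappings, mp)
    paths["mappings"] = mp
    tp = os.path.join(out_dir, "truth.json")
    with open(tp, "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    paths["truth"] = tp
    if expr is not None:
        ep = os.path.join(out_dir, "expression.tsv")
        expr.values.to_csv(ep, sep="\t", index_label="gene")
        dp = os.path.join(out_dir, "design.tsv")
        pd.DataFrame(
            {"sample": list(expr.samples), "class": [expr.labels[s] for s in expr.samples]}
        ).to_csv(dp, sep="\t", index=False)
        paths["expression"], paths["design"] = ep, dp
    if dge is not None:
        gp = os.path.join(out_dir, "dge.tsv")
        dge.table.to_csv(gp, sep="\t", index=False)
        paths["dge"] = gp
    return paths
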