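"""Readers and writers for the plain-text formats the toolkit exchanges.

Formats
-------
GMT          tab-separated gene sets: ``set_id<TAB>description<TAB>gene...``
.rnk         two columns, ``gene<TAB>score``, no header
expression   TSV, first column gene symbol, remaining columns samples (header)
design       TSV, two columns ``sample<TAB>class`` (header)
gene list    one HGNC symbol per line
DGE          TSV with columns ``gene``, ``log2fc``, ``padj`` (header)
mapping      TSV with the seven columns of the curated cross-database
             pathway mapping table (header)

All gene identifiers are treated as HGNC symbols and uppercased on input;
no alias resolution is attempted.  Parsers reject structurally invalid
input with an error naming the offending line rather than repairing it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

MAPPING_COLUMNS = [
    "source_db",
    "source_id",
    "source_name",
    "relation",
    "target_db",
    "target_id",
    "target_name",
]

RELATION_EQUIVALENT = "equivalentTo"
RELATION_PART_OF = "isPartOf"
RELATIONS = frozenset({RELATION_EQUIVALENT, RELATION_PART_OF})


def normalize_symbol(symbol: str) -> str:
    """Uppercase + strip; idempotent HGNC-symbol normalization."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named pathway gene set from one database."""

    set_id: str
    name: str
    database: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """All gene sets of one database (or of the merged meta-database)."""

    database: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        if not self.database:
            raise ValidationError("collection database label must be non-empty")
        seen: set[str] = set()
        for gs in self.sets:
            if gs.set_id in seen:
                raise ValidationError(
                    f"duplicate set_id {gs.set_id!r} in collection {self.database!r}"
                )
            seen.add(gs.set_id)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for gs in self.sets:
            if gs.set_id == set_id:
                return gs
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list[str]:
        return [gs.set_id for gs in self.sets]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.sets:
            out |= gs.genes
        return frozenset(out)


@dataclass
class ExpressionDataset:
    """Genes x samples matrix with a two-class sample labelling.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample
    columns; ``labels`` maps every sample to one of exactly two classes.
    """

    values: pd.DataFrame
    labels: dict[str, str]

    def __post_init__(self):
        samples = list(self.values.columns)
        missing = [s for s in samples if s not in self.labels]
        if missing:
            raise ValidationError(
                f"samples missing from design: {', '.join(map(str, missing))}"
            )
        classes = sorted({self.labels[s] for s in samples})
        if len(classes) != 2:
            raise ValidationError(
                f"expected exactly two classes, found {len(classes)}: {classes}"
            )
        for cls in classes:
            n = sum(1 for s in samples if self.labels[s] == cls)
            if n < 2:
                raise ValidationError(f"class {cls!r} has {n} sample(s); need >= 2")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene rows after normalization")
        arr = self.values.to_numpy()
        if not (arr == arr).all() or not (abs(arr) < math.inf).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def classes(self) -> tuple[str, str]:
        a, b = sorted({self.labels[s] for s in self.samples})
        return a, b

    def class_columns(self, cls: str) -> list[str]:
        return [s for s in self.samples if self.labels[s] == cls]


@dataclass
class RankedList:
    """Genes ordered by a real-valued score, descending.

    Ties in the input score are broken by symbol (ascending) so that
    downstream running-sum statistics are deterministic.
    """

    genes: list[str]
    scores: list[float]

    def __post_init__(self):
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked list contains duplicate genes")
        for s in self.scores:
            if not math.isfinite(s):
                raise ValidationError("ranked list contains non-finite scores")
        order = sorted(
            range(len(self.genes)), key=lambda i: (-self.scores[i], self.genes[i])
        )
        self.genes = [self.genes[i] for i in order]
        self.scores = [float(self.scores[i]) for i in order]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class DGETable:
    """Differential-expression results: gene, log2 fold change, adjusted p."""

    table: pd.DataFrame  # columns: gene, log2fc, padj

    def __post_init__(self):
        t = self.table
        for col in ("gene", "log2fc", "padj"):
            if col not in t.columns:
                raise ValidationError(f"DGE table missing column {col!r}")
        if t["gene"].duplicated().any():
            dup = t.loc[t["gene"].duplicated(), "gene"].iloc[0]
            raise ValidationError(f"duplicate gene in DGE table: {dup!r}")
        if not t["log2fc"].map(math.isfinite).all():
            raise ValidationError("non-finite log2fc in DGE table")
        bad = ~t["padj"].between(0.0, 1.0)
        if bad.any():
            raise ValidationError(
                f"padj outside [0,1] for gene {t.loc[bad, 'gene'].iloc[0]!r}"
            )

    def log2fc(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["log2fc"]))

    def padj(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["padj"]))


@dataclass(frozen=True)
class MappingRecord:
    """One row of the curated cross-database pathway mapping table."""

    source_db: str
    source_id: str
    source_name: str
    relation: str
    target_db: str
    target_id: str
    target_name: str

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValidationError(
                f"unknown relation {self.relation!r}; expected one of {sorted(RELATIONS)}"
            )
        if not self.source_id or not self.target_id:
            raise ValidationError("mapping record with empty pathway id")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path, database: str | None = None) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields
    (id, description, one or more genes).  Symbols are uppercased and
    de-duplicated; empty gene fields are dropped.  The collection label
    defaults to the file stem.
    """
    import os

    if database is None:
        database = os.path.splitext(os.path.basename(str(path)))[0]
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} field(s); need id, description "
                    "and at least one gene",
                    path=path,
                    line=lineno,
                )
            set_id, name = fields[0], fields[1]
            if set_id in seen:
                raise ParseError(
                    f"duplicate set_id {set_id!r}", path=path, line=lineno
                )
            genes = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise ParseError(
                    f"gene set {set_id!r} has no non-empty gene fields",
                    path=path,
                    line=lineno,
                )
            seen.add(set_id)
            sets.append(GeneSet(set_id=set_id, name=name, database=database, genes=genes))
    return GeneSetCollection(database=database, sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection as GMT.  Tabs are the field delimiter, so a tab
    inside an id or name is an error rather than silently sanitized."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection.sets:
            if "\t" in gs.set_id or "\t" in gs.name:
                raise ValidationError(
                    f"set {gs.set_id!r}: tab character in id or name is not "
                    "representable in GMT"
                )
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# mapping table
# ---------------------------------------------------------------------------


def read_mapping_table(path) -> list[MappingRecord]:
    """Read the seven-column TSV dialect of the pathway mapping table.

    The published mapping file is an Excel workbook; converting it is a
    one-liner documented in ``docs/methods.md``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError("mapping file is empty (header required)", path=path)
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"mapping table missing column(s): {', '.join(missing)}", path=path
        )
    records: list[MappingRecord] = []
    for i, row in df.iterrows():
        rel = row["relation"].strip()
        if rel not in RELATIONS:
            raise ParseError(
                f"unknown relation {rel!r} (row {i + 2}); expected one of "
                f"{sorted(RELATIONS)}",
                path=path,
                line=i + 2,
            )
        records.append(
            MappingRecord(
                source_db=row["source_db"].strip(),
                source_id=row["source_id"].strip(),
                source_name=row["source_name"].strip(),
                relation=rel,
                target_db=row["target_db"].strip(),
                target_id=row["target_id"].strip(),
                target_name=row["target_name"].strip(),
            )
        )
    return records


def write_mapping_table(records: list[MappingRecord], path) -> None:
    df = pd.DataFrame(
        [
            [r.source_db, r.source_id, r.source_name, r.relation,
             r.target_db, r.target_id, r.target_name]
            for r in records
        ],
        columns=MAPPING_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one HGNC symbol per line; normalized, unique,
    input order preserved."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            sym = normalize_symbol(raw)
            if not sym:
                continue
            if sym not in seen:
                seen.add(sym)
                out.append(sym)
    if not out:
        raise ParseError("gene list is empty", path=path)
    return out


def read_rnk(path) -> RankedList:
    """Two-column ``gene<TAB>score`` ranked list, no header."""
    genes: list[str] = []
    scores: list[float] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f".rnk line has {len(fields)} field(s); need gene<TAB>score",
                    path=path,
                    line=lineno,
                )
            sym = normalize_symbol(fields[0])
            if sym in seen:
                raise ParseError(f"duplicate gene {sym!r}", path=path, line=lineno)
            try:
                score = float(fields[1])
            except ValueError:
                raise ParseError(
                    f"non-numeric score {fields[1]!r} for gene {sym!r}",
                    path=path,
                    line=lineno,
                )
            if not math.isfinite(score):
                raise ParseError(
                    f"non-finite score for gene {sym!r}", path=path, line=lineno
                )
            seen.add(sym)
            genes.append(sym)
            scores.append(score)
    if not genes:
        raise ParseError(".rnk file is empty", path=path)
    return RankedList(genes=genes, scores=scores)


def read_design(path) -> dict[str, str]:
    """Two-column design TSV (``sample<TAB>class``, header required)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError("design file is empty (header required)", path=path)
    if df.shape[1] < 2:
        raise ParseError("design file needs two columns: sample, class", path=path)
    sample_col, class_col = df.columns[0], df.columns[1]
    if df[sample_col].duplicated().any():
        dup = df.loc[df[sample_col].duplicated(), sample_col].iloc[0]
        raise ParseError(f"duplicate sample {dup!r} in design", path=path)
    labels = dict(zip(df[sample_col].str.strip(), df[class_col].str.strip()))
    classes = sorted(set(labels.values()))
    if len(classes) != 2:
        raise ValidationError(
            f"design must define exactly two classes, found {len(classes)}: {classes}"
        )
    return labels


def read_expression(path, design_path) -> ExpressionDataset:
    """Expression TSV (first column gene, remaining columns samples) joined
    with its design file.

    Duplicate gene rows are collapsed to the row with the highest mean
    expression (a common preprocessing convention before ranking); the
    collapse is logged.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ParseError("expression file is empty", path=path)
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ParseError(
            f"non-numeric expression column(s): {', '.join(map(str, non_numeric))}",
            path=path,
        )
    df.index = [normalize_symbol(str(g)) for g in df.index]
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene row(s) by maximum mean", n_dup)
        order = df.mean(axis=1).to_numpy().argsort(kind="stable")
        df = df.iloc[order]
        df = df[~pd.Index(df.index).duplicated(keep="last")].sort_index()
    labels = read_design(design_path)
    extra = [s for s in df.columns if s not in labels]
    if extra:
        raise ValidationError(
            f"sample(s) in expression matrix missing from design: "
            f"{', '.join(map(str, extra))}"
        )
    labels = {s: labels[s] for s in df.columns}
    classes = sorted(set(labels.values()))
    if len(classes) != 2:
        raise ValidationError(
            f"expression samples cover {len(classes)} class(es); need exactly two"
        )
    return ExpressionDataset(values=df, labels=labels)


def read_dge(path) -> DGETable:
    """DGE TSV with columns gene, log2fc, padj (header required)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ParseError("DGE file is empty (header required)", path=path)
    missing = [c for c in ("gene", "log2fc", "padj") if c not in df.columns]
    if missing:
        raise ParseError(
            f"DGE table missing column(s): {', '.join(missing)}", path=path
        )
    df = df.copy()
    df["gene"] = df["gene"].map(lambda g: normalize_symbol(str(g)))
    return DGETable(table=df[["gene", "log2fc", "padj"]])


def read_tabular_inputs(path, kind: str, design_path=None):
    """Dispatch to the reader for ``kind`` in
    {gene_list, rnk, expression, design, dge}."""
    if kind == "gene_list":
        return read_gene_list(path)
    if kind == "rnk":
        return read_rnk(path)
    if kind == "expression":
        if design_path is None:
            raise ValidationError("expression input requires a design file")
        return read_expression(path, design_path)
    if kind == "design":
        return read_design(path)
    if kind == "dge":
        return read_dge(path)
    raise ValidationError(f"unknown input kind {kind!r}")
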