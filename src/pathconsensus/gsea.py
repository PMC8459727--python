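"""Gene set enrichment analysis (two-group and pre-ranked).

Genes are ranked by a differential metric (default: signal-to-noise).
For a gene set S within a ranking of N genes, a running sum walks the
ranking, stepping up by |score|^w / sum_{hits} |score|^w at members of S
and down by 1 / (N - |S|) elsewhere; the enrichment score (ES) is the
signed maximum deviation of this walk.  Significance comes from a
permutation null — phenotype (class-label) permutation with re-ranking
for expression input, gene-set permutation for pre-ranked input.  The
normalized enrichment score (NES) divides the observed ES by the mean
magnitude of same-sign null ES values; nominal p-values are one-sided
tail frequencies in the same-sign null (add-one smoothed), and the FDR q
is the classic ratio-of-tails estimate on the pooled normalized null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .errors import ValidationError
from .io_formats import ExpressionDataset, GeneSetCollection, RankedList

logger = logging.getLogger(__name__)

DEFAULT_B = 1000
DEFAULT_WEIGHT = 1.0
DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500

METRICS = ("signal_to_noise", "log2_ratio_of_means", "t_like")

_SD_FLOOR_FRACTION = 0.2  # per-class sd floored at this fraction of |mean|
_SD_EPS = 1e-8


@dataclass
class GSEAResult:
    """Per gene-set enrichment record."""

    set_id: str
    database: str
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    size: int  # |S ∩ ranked genes|
    leading_edge: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------


def _class_moments(x: np.ndarray, mask: np.ndarray):
    """Mean and unbiased sd over the columns selected by ``mask``."""
    sub = x[:, mask]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    return mu, sd


def _floored_sd(sd: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return np.maximum(sd, np.maximum(_SD_FLOOR_FRACTION * np.abs(mu), _SD_EPS))


def _metric_scores(
    x: np.ndarray, mask_a: np.ndarray, metric: str
) -> np.ndarray:
    """Per-gene scores for class A (mask) vs class B (complement)."""
    mask_b = ~mask_a
    if metric == "signal_to_noise":
        mu_a, sd_a = _class_moments(x, mask_a)
        mu_b, sd_b = _class_moments(x, mask_b)
        return (mu_a - mu_b) / (_floored_sd(sd_a, mu_a) + _floored_sd(sd_b, mu_b))
    if metric == "t_like":
        mu_a, sd_a = _class_moments(x, mask_a)
        mu_b, sd_b = _class_moments(x, mask_b)
        n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
        denom = np.sqrt(
            _floored_sd(sd_a, mu_a) ** 2 / n_a + _floored_sd(sd_b, mu_b) ** 2 / n_b
        )
        return (mu_a - mu_b) / denom
    if metric == "log2_ratio_of_means":
        mu_a = x[:, mask_a].mean(axis=1)
        mu_b = x[:, mask_b].mean(axis=1)
        if np.any(mu_a <= 0) or np.any(mu_b <= 0):
            raise ValidationError(
                "log2_ratio_of_means requires strictly positive class means; "
                "use signal_to_noise for log-scale data"
            )
        return np.log2(mu_a / mu_b)
    raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")


def rank_genes(
    expr: ExpressionDataset,
    metric: str = "signal_to_noise",
    positive_class: str | None = None,
) -> RankedList:
    """Rank all genes by a two-group differential metric, descending.

    ``positive_class`` names the class whose up-regulation yields positive
    scores; it defaults to the alphabetically first class label.  For
    variance-based metrics each class needs at least two samples, and the
    per-class standard deviation is floored at
    ``max(0.2 * |mean|, 1e-8)`` so that low-variance genes cannot blow up
    the ratio.  Ties are broken by gene symbol.
    """
    a, b = expr.classes
    if positive_class is None:
        positive_class = a
    if positive_class not in (a, b):
        raise ValidationError(
            f"positive_class {positive_class!r} is not one of the dataset "
            f"classes {a!r}, {b!r}"
        )
    samples = expr.samples
    mask_a = np.array([expr.labels[s] == positive_class for s in samples])
    if metric in ("signal_to_noise", "t_like"):
        if mask_a.sum() < 2 or (~mask_a).sum() < 2:
            raise ValidationError(
                f"metric {metric!r} needs >= 2 samples per class; "
                "use log2_ratio_of_means for singleton classes"
            )
    x = expr.values.to_numpy(dtype=float)
    scores = _metric_scores(x, mask_a, metric)
    return RankedList(genes=list(expr.genes), scores=[float(s) for s in scores])


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _running_sum(absw: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """Weighted Kolmogorov-Smirnov-like running sum over one ranking.

    ``absw``: |score|^w in ranking order; ``hit``: boolean membership.
    """
    n = absw.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValidationError("gene set has no genes in the ranked list")
    if n_hit == n:
        raise ValidationError(
            "gene set covers every ranked gene; miss penalty undefined"
        )
    nr = float(absw[hit].sum())
    if nr == 0.0:
        raise ValidationError(
            "all hit scores are zero at this weight; enrichment score undefined"
        )
    steps = np.where(hit, absw / nr, -1.0 / (n - n_hit))
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList, genes, w: float = DEFAULT_WEIGHT
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running sum and leading edge for one gene set.

    The ES is the running-sum value of greatest magnitude (positive
    preferred on an exact tie).  The leading edge contains the hits at or
    before the maximum (positive ES) or at or after the minimum
    (negative ES).
    """
    gene_arr = np.array(ranked.genes)
    members = {g for g in genes}
    hit = np.isin(gene_arr, list(members))
    absw = np.abs(np.asarray(ranked.scores, dtype=float)) ** w
    rs = _running_sum(absw, hit)
    i_max = int(np.argmax(rs))
    i_min = int(np.argmin(rs))
    if rs[i_max] >= -rs[i_min]:
        es = float(rs[i_max])
        leading = [g for g, h in zip(ranked.genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        es = float(rs[i_min])
        leading = [g for g, h in zip(ranked.genes[i_min:], hit[i_min:]) if h]
    if es == 0.0:
        leading = []
    return es, rs, leading


def _es_batch(absw: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """ES for many sets over one ranking.

    ``absw``: (N,) weights in ranking order; ``hits``: (n_sets, N) boolean.
    Sets must have 1 <= n_hit < N and positive hit-weight mass.
    """
    n = absw.size
    n_hit = hits.sum(axis=1)
    nr = (hits * absw).sum(axis=1)
    up = (hits * absw) / nr[:, None]
    down = (~hits) / (n - n_hit)[:, None]
    rs = np.cumsum(up - down, axis=1)
    mx = rs.max(axis=1)
    mn = rs.min(axis=1)
    return np.where(mx >= -mn, mx, mn)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def _phenotype_null_masks(
    n_samples: int, n_a: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """(B, n_samples) boolean class-A assignments.

    When the assignment space is small enough it is enumerated exhaustively
    (with a warning) instead of sampled.
    """
    total = comb(n_samples, n_a)
    if total <= B:
        logger.warning(
            "only %d distinct label assignments (< B=%d); enumerating all",
            total, B,
        )
        masks = np.zeros((total, n_samples), dtype=bool)
        for i, idx in enumerate(combinations(range(n_samples), n_a)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((B, n_samples), dtype=bool)
    for i in range(B):
        masks[i, rng.choice(n_samples, size=n_a, replace=False)] = True
    return masks


def _normalize_and_test(
    es_obs: np.ndarray, null_es: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NES, nominal p and FDR q from observed ES and a (n_sets, B) null.

    Sign-matched normalization: positive and negative null ES are averaged
    separately; each observed (and null) ES is divided by the mean
    magnitude of the same-sign null of its own set.  Nominal p is the
    add-one smoothed one-sided tail frequency within the same-sign null.
    FDR q is the ratio-of-tails estimate over the pooled normalized null.
    """
    n_sets, B = null_es.shape
    nes = np.zeros(n_sets)
    p_nom = np.ones(n_sets)
    null_nes_rows: list[np.ndarray] = []

    pos_mean = np.zeros(n_sets)
    neg_mean = np.zeros(n_sets)
    for s in range(n_sets):
        null = null_es[s]
        pos = null[null > 0]
        neg = null[null < 0]
        pos_mean[s] = pos.mean() if pos.size else np.nan
        neg_mean[s] = np.abs(neg).mean() if neg.size else np.nan
        # normalized null for this set (sign-matched scaling)
        row = np.zeros_like(null)
        if pos.size:
            row[null > 0] = null[null > 0] / pos_mean[s]
        if neg.size:
            row[null < 0] = null[null < 0] / neg_mean[s]
        null_nes_rows.append(row)

        es = es_obs[s]
        if es > 0:
            scale = pos_mean[s] if pos.size else np.abs(null).mean() or 1.0
            nes[s] = es / scale
            p_nom[s] = (1 + int((pos >= es).sum())) / (1 + pos.size)
        elif es < 0:
            scale = neg_mean[s] if neg.size else np.abs(null).mean() or 1.0
            nes[s] = es / scale
            p_nom[s] = (1 + int((neg <= es).sum())) / (1 + neg.size)
        else:
            nes[s] = 0.0
            p_nom[s] = 1.0

    pooled = np.concatenate(null_nes_rows)
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled <= 0]
    obs_pos = nes[nes >= 0]
    obs_neg = nes[nes <= 0]
    q = np.ones(n_sets)
    for s in range(n_sets):
        v = nes[s]
        if v >= 0:
            num = (pooled_pos >= v).mean() if pooled_pos.size else 1.0
            den = (obs_pos >= v).mean() if obs_pos.size else 1.0
        else:
            num = (pooled_neg <= v).mean() if pooled_neg.size else 1.0
            den = (obs_neg <= v).mean() if obs_neg.size else 1.0
        q[s] = min(1.0, num / den) if den > 0 else 1.0
    return nes, p_nom, q


def _filter_sets(
    collection: GeneSetCollection,
    ranked_genes: list[str],
    min_size: int,
    max_size: int,
):
    """Restrict sets to the ranked universe and apply size filters."""
    universe = set(ranked_genes)
    kept = []
    for gs in collection.sets:
        inside = gs.genes & universe
        size = len(inside)
        if size < min_size or size > max_size:
            logger.info(
                "gene set %s filtered by size (%d not in [%d, %d])",
                gs.set_id, size, min_size, max_size,
            )
            continue
        if size >= len(ranked_genes):
            logger.warning(
                "gene set %s covers the whole ranked list; excluded", gs.set_id
            )
            continue
        kept.append((gs, inside))
    return kept


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------


def run_gsea(
    expr: ExpressionDataset,
    collection: GeneSetCollection,
    B: int = DEFAULT_B,
    scheme: str = "phenotype",
    seed: int | None = None,
    metric: str = "signal_to_noise",
    w: float = DEFAULT_WEIGHT,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    positive_class: str | None = None,
) -> list[GSEAResult]:
    """Two-group GSEA with a phenotype-permutation null.

    Each permutation reassigns class labels (preserving class sizes) and
    re-ranks all genes before recomputing every set's ES, so gene-gene
    correlation is preserved in the null.  Results are bit-reproducible
    given ``seed``.
    """
    if scheme != "phenotype":
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    if B < 1:
        raise ValidationError("B must be >= 1")
    if B < 100:
        logger.warning("B=%d is small; p-values will be coarse (B >= 100 advised)", B)
    rng = np.random.default_rng(seed)

    ranked = rank_genes(expr, metric=metric, positive_class=positive_class)
    kept = _filter_sets(collection, ranked.genes, min_size, max_size)
    if not kept:
        return []

    # observed ES / leading edges on the tie-broken observed ranking
    es_obs = np.zeros(len(kept))
    leading: list[list[str]] = []
    for i, (gs, inside) in enumerate(kept):
        es, _, le = enrichment_score(ranked, inside, w=w)
        es_obs[i] = es
        leading.append(le)

    # permutation null: re-rank under permuted labels
    a, b_cls = expr.classes
    pos_cls = positive_class if positive_class is not None else a
    samples = expr.samples
    n_a = sum(1 for s in samples if expr.labels[s] == pos_cls)
    masks = _phenotype_null_masks(len(samples), n_a, B, rng)

    x = expr.values.to_numpy(dtype=float)
    gene_order_key = np.argsort(np.argsort(np.array(expr.genes)))  # symbol rank
    hit_base = np.zeros((len(kept), x.shape[0]), dtype=bool)
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    for i, (gs, inside) in enumerate(kept):
        hit_base[i, [gene_index[g] for g in inside]] = True

    null_es = np.zeros((len(kept), masks.shape[0]))
    for p in range(masks.shape[0]):
        scores = _metric_scores(x, masks[p], metric)
        order = np.lexsort((gene_order_key, -scores))
        absw = np.abs(scores[order]) ** w
        null_es[:, p] = _es_batch(absw, hit_base[:, order])

    nes, p_nom, q = _normalize_and_test(es_obs, null_es)
    return [
        GSEAResult(
            set_id=gs.set_id, database=gs.database,
            es=float(es_obs[i]), nes=float(nes[i]),
            p_nominal=float(p_nom[i]), q_fdr=float(q[i]),
            size=len(inside), leading_edge=leading[i],
        )
        for i, (gs, inside) in enumerate(kept)
    ]


def run_prerank(
    ranked: RankedList,
    collection: GeneSetCollection,
    B: int = DEFAULT_B,
    seed: int | None = None,
    w: float = DEFAULT_WEIGHT,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[GSEAResult]:
    """Pre-ranked GSEA with a gene-set-permutation null.

    The null for a set of size m is the ES distribution of B random
    m-gene subsets of the ranked universe.  An all-zero score vector is
    rejected as a degenerate ranking.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    scores = np.asarray(ranked.scores, dtype=float)
    if np.all(scores == 0):
        raise ValidationError("all ranked scores are zero; degenerate ranking")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    kept = _filter_sets(collection, ranked.genes, min_size, max_size)
    if not kept:
        return []
    absw = np.abs(scores) ** w

    es_obs = np.zeros(len(kept))
    leading: list[list[str]] = []
    null_es = np.zeros((len(kept), B))
    for i, (gs, inside) in enumerate(kept):
        es, _, le = enrichment_score(ranked, inside, w=w)
        es_obs[i] = es
        leading.append(le)
        m = len(inside)
        hits = np.zeros((B, n), dtype=bool)
        for bdx in range(B):
            hits[bdx, rng.choice(n, size=m, replace=False)] = True
        # guard: a random set may land entirely on zero-weight genes
        nr = (hits * absw).sum(axis=1)
        bad = nr == 0
        while bad.any():
            for bdx in np.flatnonzero(bad):
                hits[bdx] = False
                hits[bdx, rng.choice(n, size=m, replace=False)] = True
            nr = (hits * absw).sum(axis=1)
            bad = nr == 0
        null_es[i] = _es_batch(absw, hits)

    nes, p_nom, q = _normalize_and_test(es_obs, null_es)
    return [
        GSEAResult(
            set_id=gs.set_id, database=gs.database,
            es=float(es_obs[i]), nes=float(nes[i]),
            p_nominal=float(p_nom[i]), q_fdr=float(q[i]),
            size=len(inside), leading_edge=leading[i],
        )
        for i, (gs, inside) in enumerate(kept)
    ]


def gsea_results_frame(results: list[GSEAResult], alpha: float = 0.05):
    """Tabular view (pandas) of GSEA results, sorted by q then |NES|."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "set_id": r.set_id, "database": r.database,
                "es": r.es, "nes": r.nes,
                "p_nominal": r.p_nominal, "q_fdr": r.q_fdr,
                "size": r.size,
                "leading_edge": ",".join(r.leading_edge),
                "significant": r.q_fdr < alpha,
            }
            for r in results
        ]
    )
    if not df.empty:
        df = df.sort_values(
            ["q_fdr", "p_nominal", "set_id"]
        ).reset_index(drop=True)
    return df
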