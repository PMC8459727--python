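# Methods

This note records the statistical procedures the package implements,
the defaults it commits to, and the choices made where the design was
genuinely open.

## Over-representation analysis

The hypergeometric upper tail P(X ≥ k) is computed as a ratio of exact
Python integers and rounded once to a float, so it is correct to ≤ 0.5
ulp at any problem size — including far tails where a complement-based
survival function (1 − CDF) would lose all relative precision.  The
summation runs over at most min(n, K) − max(0, n+K−N) + 1 terms;
`math.comb` on bignums keeps this fast even for genome-scale universes
(N ≈ 20,000).  We deliberately preferred exact integer arithmetic over
a log-space compensated summation: it is simpler, strictly more
accurate, and the term count is small.

Multiple-testing correction uses Benjamini–Yekutieli (via
`statsmodels.stats.multitest`), which controls the FDR under arbitrary
dependence — appropriate because gene sets within a database overlap
heavily.  Correction scope is per database: each database is analyzed
as its own experiment, matching the per-database result tables the
consensus layer consumes.  Correcting across databases would couple a
group's calls through the correction itself and blur the
concordant/contradictory distinction.

Defaults: the universe is the union of the collection's genes
(overridable with a measured background — the honest choice when one is
available); gene-set size filter 3–1000 genes within the universe;
α = 0.05 drives significance flags only, never the p-values.

## GSEA

The two-group method is the canonical weighted Kolmogorov–Smirnov-like
statistic:

* **Ranking metric** (default signal-to-noise): per-class unbiased
  standard deviations are floored at max(0.2·|mean|, 1e-8), the usual
  guard against near-constant genes dominating the ranking.  Ties are
  broken by gene symbol so the ranking — and everything downstream — is
  deterministic.
* **ES**: running sum stepping +|score|^w/N_R on hits (N_R = total hit
  weight, default w = 1) and −1/(N − |S|) on misses; ES is the value of
  greatest magnitude, positive preferred on an exact tie.  The leading
  edge is the hits at or before the maximum (positive ES) or at or
  after the minimum (negative ES).
* **Null**: phenotype permutation with full re-ranking per permutation
  (preserves gene–gene correlation); when the label-assignment space is
  smaller than B it is enumerated exhaustively with a warning.
  Pre-ranked input instead permutes gene sets (random same-size subsets
  of the ranking).
* **NES / p / q**: sign-matched normalization (positive and negative
  null ES scaled separately by their mean magnitudes); nominal p is the
  add-one smoothed one-sided tail frequency within the same-sign null,
  so it is never exactly zero; FDR q is the classic ratio-of-tails
  estimate on the pooled normalized null.  If a set has no same-sign
  null values (possible only at very small B), the mean |null ES| is
  used as a fallback scale.

Defaults: B = 1000 permutations, w = 1, signal-to-noise metric,
size filter 5–500.  All are surfaced as arguments/flags and recorded in
run metadata; they are this package's defaults for the canonical
method, not a claim about any particular external tool's settings.
A single seeded `numpy` generator drives all permutations; identical
seeds give bit-identical result tables.

## Equivalence groups and hierarchy

`equivalentTo` is treated as a true equivalence relation: groups are
connected components of the mapping graph, so A≡B and B≡C merge A and C
even when never directly mapped.  Merged gene sets are exact unions.
Group identifiers are `DC:` plus a zero-padded ordinal assigned after
sorting components by their smallest member, making ids stable under
input order; singleton pathways keep their original identifiers.
Group display names take the name of the lexicographically smallest
member.

`isPartOf` edges attach to the merged node when the endpoint pathway
belongs to a group (the group is the unit of analysis, so the hierarchy
should show it once).  Validation: cycles are fatal; depth is counted
with the root category at depth 1 and flagged beyond 4 (the published
curated hierarchy satisfies ≤ 4); orphans are warnings.  The
circle-pack export converts the DAG to a tree by duplicating
multi-parent nodes under each parent — a standard layout requirement —
so total leaf appearances can exceed the DAG's leaf count.

Results uploaded from external methods (topology-based or otherwise)
enter through `ImportedResultTable` and flow through the same
classification, declared as score-based when they carry a signed score.

## Consensus labels

Significance is "adjusted statistic < α" per database (ORA: BY-adjusted
p; GSEA: FDR q).  Labels partition the multi-database groups:
direction conflict (≥ 2 significant members with opposing NES signs)
takes precedence, then mixed significance, then all-significant, then
none-significant.  The all-non-significant case gets its own label
(`concordant_nonsignificant`) rather than being folded into
"concordant": both conventions for counting concordance remain
computable from the output.  Absence is never non-significance: a
database without a result for a pathway simply drops out of that
group's comparison, and single-database groups are reported separately
as incomparable.  Cross-method comparison counts a group as concordant
under a method when its label is `concordant_significant`.

## Synthetic data generator

The generator emulates the two structural features the pipeline feeds
on: (1) families of overlapping gene-set collections with known
equivalences — each truth pathway appears once per database as a
variant sharing an integer-sized core chosen so every pairwise Jaccard
falls in the requested interval (default 0.5–0.8, roughly the overlap
real equivalent pathways exhibit), groups drawing disjoint gene pools;
(2) two-group expression on the log2 scale: null genes
Normal(6, 1) in both groups, planted genes shifted by ±effect·σ in the
case group.  Because values are already log2, the expected log2 fold
change of a planted gene is ±effect·σ directly.  Defaults: 2,000-gene
universe, 10 groups × 3 databases × 50 genes per set, effect 1.0,
20 vs 20 samples.

The companion DGE table (Welch t-test, Benjamini–Hochberg) is a fixture
convenience supporting the gene-level annotations, not a count-model
analysis.  The generator does not emulate read-count noise,
library-size effects, batch structure, gene–gene correlation, or
realistic pathway topology — so passing tests demonstrate the
statistical machinery is correct and calibrated under a clean Gaussian
model, not that any particular biological dataset will behave as
cleanly.

The discordance construction plants signal only in the genes exclusive
to one database's variant, with effect 2.0: it mirrors the empirical
pattern where the genes unique to one database's version of a pathway
are strongly over-expressed while the shared core is flat, which is
what produces cross-database contradictions in practice.

## Numerical and interface choices

* Parsers reject structurally invalid input with the offending
  line/column named; nothing is silently repaired.  Symbols are
  uppercased (idempotent); no alias resolution — out-of-vocabulary
  symbols are kept and simply fail to intersect.
* Duplicate expression rows for one symbol collapse to the row with the
  highest mean (common pre-ranking convention), logged.
* Ranked-list ties: (score descending, symbol ascending), fixed once at
  parse time.
* The published cross-database mapping workbook is consumed as a
  seven-column TSV; converting the Excel original is a one-liner —
  `pandas.read_excel(path).to_csv(out, sep="\t", index=False)` with the
  columns renamed to `source_db, source_id, source_name, relation,
  target_db, target_id, target_name`.
* Venn decomposition is capped at 4 sets (legibility of the diagram and
  the four-database use case); wider groups fall back to pairwise
  overlap tables.  Histogram bins default to 21 equal-width bins over
  the observed log2FC range symmetrized about 0; edges are recorded in
  the output.  Whether to restrict the histogram to significant genes
  is left to a `max_padj` flag (default: annotate all region genes
  present in the DGE table).

## Problem sizes used in checks

The statistical checks run at desk scale by design: the exact-tail
sweep covers every configuration with N ≤ 30 (~87,000 cases); ES
equivalence uses 1,000 random rankings with N ≤ 50; GSEA calibration
uses 200 ten-gene sets at B = 500 and recovery uses the generator's
default conditions over 20 replicate seeds; set-algebra checks cover
10,000 random families.  These sizes make the full suite run in well
under a minute of compute per pillar while leaving the estimators'
Monte-Carlo error small relative to the asserted tolerances.

## Known limitations

* GSEA q-values are the ratio-of-tails estimator, which is noisy at
  small B and not monotone in NES; interpret q near the threshold with
  the usual caution.
* ORA's default gene-set universe overstates enrichment relative to a
  measured background; supply one when you have it.
* The consensus layer compares calls, not effect sizes; a future
  combined cross-database score is explicitly out of scope.
* The hierarchy validator checks structure only; it cannot detect
  semantically wrong (but acyclic) curated relations.
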