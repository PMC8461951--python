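# Methods

This note documents the statistical procedures implemented in `sigmap`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that
affect reproducibility.

## Co-expression mapping

### Quantile normalization

Reference compendia pooled from several experiments are harmonized by
quantile normalization: with X the features × samples matrix, the
reference distribution is the across-sample mean of order statistics,
`ref = mean_j(sort(X[:, j]))`, and each sample's values are replaced by
`ref` according to their within-sample ranks. Tied values within a sample
all receive the mean of the order statistics their positions span, so the
transform is well defined on discrete data.

Two implementation details matter for exactness. First, the defining
property — all post-normalization sorted sample vectors identical — holds
bitwise, not approximately. Second, when the input is already harmonized
(all sorted columns equal), the reference distribution is taken directly
from the shared sorted column rather than recomputed as a mean of
identical values; mathematically the same number, but it keeps repeated
normalization bit-exactly idempotent (floating-point summation of k
identical values need not return the value for k not a power of two).
With tie groups of three or more values, idempotence is exact up to
1-ulp rounding in the group mean.

### Correlation and clustering

For one signature direction, the compendium is restricted to the
signature features (absent features are reported, zero overlap is an
error) and the Pearson correlation r_ij of every feature pair across the
reference samples is computed. Features with zero variance across the
compendium cannot be correlated and are excluded with a report. At least
three reference samples are required.

Hierarchical clustering uses average linkage (UPGMA) on Euclidean
distances. By default each feature is represented by its **row of the
correlation matrix** — its vector of correlations to all signature
features — and distances are Euclidean between those rows; this is the
most literal reading of "clustering the gene-to-gene correlation matrix".
The alternative of using 1 − r directly as the pairwise dissimilarity is
available (`representation="dissimilarity"`); on clean block structure
both recover the same clusters, but they are not equivalent in general,
so the choice is surfaced rather than hidden.

The linkage engine is SciPy's `linkage(method="average")`. Its merge
history is validated against an independent greedy O(n³) UPGMA
implementation (lowest-index pair first on ties) across hundreds of
random instances; on continuous data exact distance ties have probability
zero and the two agree merge-for-merge. SciPy's output is deterministic
for a fixed input, which is what downstream reproducibility relies on.

### Cutting and attribution

Published analyses of this kind usually identify co-expression clusters
visually ("boxed" on a heatmap). A reproducible pipeline needs a rule,
so the cut is explicit: a fixed cluster count k, a merge-height
threshold, or — the default — the k ∈ [2, 10] maximizing the mean
silhouette coefficient on the clustered representation. Cluster labels
are relabeled by first occurrence so they are stable across runs.

For display and attribution, each feature is z-scored across the
reference samples and clipped to [−2, +2] (the conventional heatmap
scale: red above the feature mean, blue below, saturating at two standard
deviations). The attribution score of cluster c for reference group g is
the mean clipped z-score over the features of c and the samples of g;
groups are ranked per cluster and the top group names the cluster. The
score is invariant under permutation of samples within a group. Ordered
heatmaps are exported together with their numeric matrix so figures can
be regenerated bit-exactly.

## Differential expression

`score_two_group` applies, per feature, Welch's unequal-variance t test
(default) or the asymptotic rank-sum test, two-sided. Multiple testing
defaults to Benjamini–Hochberg; `mt_procedure="none"` reproduces raw
p-value thresholding, and Bonferroni is available. Fold changes are
ratios of linear-scale group means (log2 input is exponentiated first),
so a planted log2 shift of log2(1.2) realizes exactly FC 1.2 in the
noise-free limit. The signature is the set of features with adjusted
p < α (default 0.05), split into up/down by the sign of the log fold
change. A feature with zero variance in both groups is assigned statistic
0 and p 1 rather than raising, as the contract requires — even in the
degenerate case of two distinct constants, which the t statistic cannot
rank anyway.

`score_pairwise_concordance` is a distribution-free alternative scoring
idiom: for each feature, the fraction f of all case × control pairs with
case > control (ties half-weighted), reported as 200·(f − ½) ∈
[−100, 100]. It is computed through the Mann-Whitney identity
U = R_case − n(n+1)/2 on per-feature ranks and is invariant under any
strictly monotone transform of the data. It is an analogue of
score-above-threshold selection schemes used with pairwise chip
comparisons, not a reconstruction of any particular unpublished formula.

A covariate hook, `center_batches`, removes per-feature batch means
(adding the grand mean back) before scoring, for cohorts pooled over
sequencing or hybridization batches. No negative-binomial GLM or
moderated-variance estimation is included; those belong to dedicated DE
packages, and the substance here is downstream of the gene list.

## Enrichment

Over-representation of a query gene list against a GMT collection uses
the upper-tail hypergeometric probability P[X ≥ k] with universe size N,
set size K (after intersecting each set with the universe), query size n
and overlap k, BH-adjusted across the collection. The universe defaults
to all features measured on the platform after annotation — the standard
over-representation convention. Probe-set clusters are translated to gene
symbols through the annotation map with duplicates collapsed; clusters
below 5 mapped genes are skipped. Ranked running-sum enrichment is
deliberately out of scope: the inputs here are plain gene lists.

## Sample-level statistics

* **PCA**: features centered (optionally unit-scaled; off by default,
  matching common transcriptome practice), full SVD, explained-variance
  fractions plus sample scores. Sign convention: the largest-magnitude
  loading of each component is made positive, so scores are
  deterministic.
* **Sample clustering**: the same UPGMA engine applied to samples, on
  per-feature z-scaled vectors.
* **Mann-Whitney U**: when both groups have ≤ 8 observations the
  two-sided p is computed by full permutation enumeration —
  P(|U − nm/2| ≥ |u_obs − nm/2|) over all C(n+m, n) labelings — which is
  valid under ties and coincides with the doubled single tail in the
  tie-free case (the permutation distribution of U is symmetric about
  nm/2 under exchangeability). Larger samples use the tie-corrected
  normal approximation **without** continuity correction, so that for two
  groups the p-value coincides exactly with Kruskal-Wallis (H = z²).
* **Kruskal-Wallis + Dunn**: tie-corrected H; Dunn's pairwise z-tests on
  mean ranks with the standard tie-corrected variance, Bonferroni-adjusted
  over pairs by default (Holm and unadjusted available). Bonferroni was
  chosen as the conservative default where no adjustment is conventional.
* **Welch's t with normality gate**: when requested, a per-group
  Shapiro-Wilk p at α = 0.05 is recorded alongside the test result. The
  gate is advisory (recorded, not a silent fallback), because switching
  tests on a pretest changes the procedure's operating characteristics.

## Synthetic data: what it emulates and what it does not

The generator produces three artifact families, all driven by a single
seeded PCG64 generator (`numpy.random.default_rng`); fixed seed implies
bit-identical output wherever the RNG algorithm is the same.

* **Reference compendium**: log2-scale Gaussian expression around a
  baseline (default 7.0, a mid-range log2 intensity), with co-expression
  blocks elevated by `effect_log2` (default 2.0) in declared subsets of
  reference groups, plus i.i.d. noise (default sd 0.25). The shipped
  template names 15 groups in four families — a bone-marrow
  differentiation series, blood subsets (DCs, neutrophils, classical and
  non-classical monocytes), G-CSF-treated leukocytes, and in-vitro
  stimulated monocytes — with per-family sizes 34/15/6/12 (67 samples),
  the composition typical of a myeloid reference compendium.
* **Case/control matrices**: planted features receive a log2 shift of
  ±log2(fc) in cases, with per-feature fc drawn as
  `mean_fc + N(0, fc_dispersion)` truncated just above 1. The default
  mean fold change is 1.20 — the weak-effect regime characteristic of
  purified-cell disease signatures — with noise sd 0.15 on log2 scale
  and cohort sizes 25 vs 10 in the demo. At these settings the
  per-feature effect (log2 1.2 ≈ 0.263) is large relative to its
  standard error (≈ 0.056), so detection power is high; this matters
  because at low power the fold changes of *detected* features are
  inflated by selection (winner's curse), whereas near-complete recall
  keeps the detected-feature mean FC within ±0.02 of the planted value.
  The truth table records each planted feature's direction, planted FC,
  and the FC realized in the emitted matrix.
* **Serum markers**: per-group normal or moment-matched lognormal values
  (lognormal default, as marker concentrations are positive and skewed).
  An sd of exactly 0 is the degenerate limit (all values equal the group
  mean); negative sds are rejected.

A Poisson transform (`to_counts`) converts log2 intensities to
RNA-seq-like counts for exercising count-scale inputs.

Not emulated: probe-level microarray physics, batch effects beyond the
dataset label, gene–gene correlation *within* the case/control cohort
(planted features are conditionally independent given group), library
size variation, and any real marker-gene biology. Passing tests therefore
demonstrate that the algorithms recover structure of the planted kind at
the planted effect/noise ratios — not that any particular biological
signature is correct.

## Problem sizes and tolerances in the test suite

The suite exercises: quantile normalization on a 10,000 × 70 matrix
(exact sorted-vector identity, bit-exact idempotence); UPGMA oracle
agreement on 200 random instances of up to 20 features; planted 4-block
recovery (4 × 6 reference samples, blocks of 25, noise sd 0.3) requiring
adjusted Rand index ≥ 0.9 with correct top-group attribution; DE type-I
calibration under a 10,000-feature global null at 25 vs 10 samples
(rejection fraction inside the 99% binomial band around 0.05; KS
uniformity of 500 p-values at p > 0.01); fold-change fidelity at planted
FC 1.20 (exact in the noise-free limit, detected-feature mean within
±0.02 under noise); exact-statistic agreement with exhaustive enumeration
(Mann-Whitney for all group sizes ≤ 8, hypergeometric for all universes
≤ 12); and byte-level determinism of two full pipeline runs. These sizes
were chosen as the smallest that exercise each property convincingly
while keeping the suite fast enough to run on every change.

## Known limitations

* The silhouette-based default cut is a heuristic; strongly nested or
  unbalanced block structure can favor a coarser k than planted. Pass
  `k` explicitly when the cluster count is known.
* Attribution scores are means of clipped z-scores; clipping compresses
  extreme markers, so scores saturate near ±2 and are not comparable
  across compendia with different group compositions.
* The concordance score thresholds are in score units (|score| above a
  user cut-off), not calibrated p-values.
* Quantile normalization assumes the compared samples share a global
  distribution; it will erase genuine global shifts.
* The exact Mann-Whitney path enumerates C(n+m, n) labelings and is
  gated at n, m ≤ 8 (≤ 12,870 labelings); beyond that the asymptotic
  path is used.
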