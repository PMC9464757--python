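# Methods

This note documents the models, procedures and numerical choices behind
`dualsubtype`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scoring model

A signature model assigns each class *c* a gene list *G_c* and a centroid
vector over those genes (log2 scale). A sample's score for class *c* is the
Pearson correlation between its profile restricted to *G_c* and the
centroid. Pearson correlation is the package's default because it is the
established design of nearest-centroid expression subtype classifiers and is
invariant to per-sample affine transforms (scanner gain/offset); the score
function is a parameter of `score_sample` so cosine or rank-based variants
can be substituted. Genes are **not** standardized before correlation by
default — standardization is a cohort-level preprocessing decision and is
left to the caller. The standard call is the argmax score, ties broken by
the fixed class order (Luminal, Basal, HER2) purely as a determinism
contract.

Centroids are trained as per-gene class means over labeled samples
(`train_centroids`): commercial assay centroids are proprietary and cannot
be redistributed, so the package treats the centroid values as data,
supplied by the user or trained from a labeled cohort. A class needs at
least two labeled samples; missing genes are an error (imputation is
preprocessing, out of scope). A zero-variance restriction — a constant
profile over a class's genes — raises an explicit undefined-score error
rather than silently scoring 0.

The 4-gene HER2 signature makes its correlation statistically fragile by
construction. No minimum-gene guard is imposed; instead the bootstrap
machinery (below) quantifies the resulting uncertainty, and its expected
consequence — more multi-subtype calls involving HER2 — is a documented
property, not a defect to be corrected.

## Single/dual/triple calling

The statistic of interest per sample is the top difference
*d* = score₍₁₎ − score₍₂₎ ≥ 0. Two complementary criteria decide whether the
top pair is "statistically indiscernible":

1. **Cohort threshold from multimodality detection**
   (`fit_difference_thresholds`). Per winning class, the *d* values are fit
   with 1- and 2-component Gaussian mixtures. The 2-component model is
   accepted when it wins on BIC **and** its component means are separated by
   more than the sum of their SDs (the separation guard prevents a split of
   one mode from masquerading as bimodality). The threshold is then the
   density minimum between the two component means, located by grid search
   at step 1e-4. Otherwise the threshold falls back to the 5th percentile
   of *d*, flagged `quantile-fallback`. Classes with fewer than 50 winners
   use the pooled distribution over all samples; classes with no samples get
   an undefined threshold (calling such a sample is an error, not a guess).
   Two further numerical choices: the mixture fit requires at least 20
   observations and at least 3 distinct values (otherwise the fallback is
   used directly), and the fallback percentile is computed with
   `method="lower"` so the threshold is an *observed* order statistic.

2. **Per-sample gene bootstrap** (`bootstrap_scores`). Each replicate
   resamples, independently for each class, that class's genes with
   replacement (same size as the signature) and recomputes the correlation
   on the resampled multiset; all classes draw from one RNG stream per call
   so a (seed, B) pair fully determines the replicates. The flip fraction
   of an ordered pair (i, j) is the fraction of valid replicates in which
   class j scores at least as high as class i; ties count as flips, so
   flip(i,j) + flip(j,i) ≥ 1. Replicates whose resampled restriction is
   degenerate are marked invalid; more than 50% invalid replicates aborts
   with an error. Defaults: B = 1000, alpha = 0.05.

A pair is indiscernible when *d* is **strictly below** the winning class's
threshold **or** the flip fraction exceeds alpha. The strict inequality is
deliberate: the fallback threshold is an observed *d* value, and with a
non-strict rule a degenerate cohort (all *d* equal, e.g. the noise-free
limit) would flag every sample; with the strict rule it flags none, and on
continuous data the two rules differ by at most one order statistic. The OR
combination reflects that the two criteria capture different failure modes —
a cohort-level mixture of populations vs per-sample ranking instability —
and either alone can be disabled by configuration.

Triple calling tests the (second, third) pair by the same rule, reusing the
winning class's threshold on score₍₂₎ − score₍₃₎: Triple iff both pairs are
indiscernible, Dual iff only the top pair, Single otherwise. Dual/triple
labels list components in descending observed-score order;
`canonical_label` gives the score-order-independent group name used for
cohort accounting.

These defaults (B, alpha, q, BIC selection, separation guard) are
documented reconstructions of a procedure whose published description names
only its ingredients — bootstrap plus multimodality detection — and each is
configurable.

## Synthetic cohorts

The generator emulates the statistical shape of a subtyping cohort, not any
specific dataset:

- **Composition.** Single/Dual/Triple counts and the class split of singles
  are allocated by largest-remainder rounding from the configured fractions
  (defaults: 80/12/8% Luminal/Basal/HER2, 5% dual, 0.3% triple, mirroring a
  hormone-receptor-positive-dominated registry cohort). Duals are split
  across the three class pairs proportionally to the product of class
  proportions, which makes Luminal-Basal and Luminal-HER2 the dominant dual
  types. Deterministic allocation keeps fixture sizes exact; randomness is
  confined to expression noise and clinical/outcome draws.
- **Expression.** Each signature gene *g* of class *c* has an activation
  loading *w_g*, spaced `linspace(-1, 3)` with mean exactly 1 — negative
  loadings are genes the program represses, and the wide span gives even the
  4-gene panel pairwise contrasts well above noise, as a curated on/off
  marker panel has. All samples carry a zero-mean *anti-aligned baseline*
  −(w_g − 1) on signature genes: off-state marker genes sit below their
  activated level (HER2-amplicon genes in non-amplified tumors are the
  canonical example), so inactive samples anti-correlate with the class
  centroid instead of scoring at random. An active program adds
  `activation_effect · w_g` (default 2 log2 units), scaled by
  `dual_attenuation` (default 0.7) when two or more programs are co-active —
  dual tumors show intermediate marker levels. Because the loadings average
  exactly 1 and the baseline averages exactly 0, an active signature's mean
  shift equals `activation_effect` exactly in the noise-free limit.
  Background genes (default 100) are pure Gaussian noise; `noise_sd`
  (default 0.3) applies to every gene. `noise_sd = 0` is permitted and
  well-defined throughout (the baseline keeps all restrictions
  non-constant). One caveat: `dual_attenuation · activation_effect` must
  exceed the baseline contrast (1.0) for co-active programs to correlate
  positively with their centroids; the defaults (1.4 > 1) satisfy this.
- **Clinical coupling.** Each sample's clinical subtype is drawn from a
  composition-conditional table (Luminal-singles overwhelmingly HR+HER2−,
  Basal-singles split between triple-negative and ER-low HR+HER2− disease,
  Luminal-Basal duals almost always clinically HER2−). ER% respects the HR
  stratum (< 1% when HR−) and, within HR+, has class-conditional means
  ordered Luminal-single (90) > Luminal-containing dual (60) > Basal-single
  (12); Ki67% means are ordered Luminal-single (18) < Luminal dual (38) <
  HER2-single (55) ≤ Basal-single (62); HER2 IHC/FISH is drawn consistently
  with the subtype. pCR outcomes are Bernoulli per molecular group; the
  default rates plant the HER2-single vs Luminal-HER2 contrast at
  0.613 vs 0.238 as the study condition, with the remaining groups at
  field-plausible neoadjuvant response rates (Luminal-single 0.15,
  Basal-single 0.35, other HER2-involved groups 0.30–0.45).

What the generator does **not** emulate: probe-level microarray structure,
batch effects, assay normalization, gene-gene correlation within a program
beyond the shared activation factor, or any real cohort's effect sizes.
Passing recovery tests therefore demonstrates the *mechanics* of the
classification chain under a favorable, well-specified signal model — not
performance on real tumors, where programs are noisier and partially
correlated.

## Prevalence estimation

`estimate_mixture_prevalence` draws, per iteration, round(w_k · subset_size)
samples with replacement from clinical stratum k and records the dual
fraction of the pseudo-cohort; the estimate is the mean over iterations and
the CI the 2.5/97.5 percentiles. Sampling is with replacement because small
strata (e.g. 5% HR−HER2+ of a modest cohort) must be over-sampled to meet
their quota. Since only the per-sample dual indicator enters the fraction,
the draw is realized through its sufficient statistic — the stratum's dual
count is Binomial(m_k, r̂_k) — which is distributionally identical to
index-level resampling and much faster. Triples are excluded from the
numerator by default (duals and triples are accounted separately);
`include_triple=True` adds them. Defaults subset_size = 10,000 and
n_iter = 1,000 are package choices; published analyses of this kind report
far tighter intervals, implying much larger effective resampling, which is
documented rather than chased.

## Burstein-style re-classification

The four-class TNBC classifier is the generic scoring core applied to a
4-class shared-panel model (identical results by construction, asserted in
tests). The published centroid values are deliberately not hard-coded —
they ship as user-supplied JSON config; `make_synthetic_burstein_model`
provides a clearly-labeled synthetic stand-in (random centroids) for
exercising the mechanics. Ties break in the fixed order BLIA, BLIS, LAR,
MES.

## Statistics

- Chi-square test of independence: classic Pearson statistic, **no**
  continuity correction, df = (r−1)(c−1); zero expected counts are an
  error.
- Two-sample t-test: Welch with Satterthwaite df by default (the safer
  choice when variances differ), toggleable to pooled.
- Proportions: Wilson score intervals at 95%.
- Logistic regression: maximum likelihood via Newton-Raphson/IRLS
  (statsmodels), convergence at gradient norm < 1e-8 or 100 iterations,
  Wald p-values. Constant/collinear columns and degenerate outcomes are
  rejected up front. Under separation, a fit the optimizer aborts raises
  an error; diverging-but-finite estimates (|coef| > 30) are returned
  flagged unusable with a warning.
- Ki67 is dichotomized at 30% (the low-proliferation "TNLP" range) and
  ER-low positive is 1–10% inclusive, both as tagged filters.
- No multiple-testing adjustment anywhere: all p-values are raw, by
  design, and users combining many contrasts should correct downstream.

## Problem sizes

The test suite exercises the chain at n = 400 (shared fixture) and n = 2000
(recovery checks, B = 1000 bootstrap on a 200-sample subset); the acceptance
script uses n = 2000 for recovery, 10⁷ effective resamples for prevalence,
and a 60,000-sample truth table for the treatment-response contrast. These
sizes give Monte-Carlo errors comfortably inside the tolerances asserted
while keeping a full run in seconds on one CPU.

## Known limitations

- The dual-calling procedure is a reconstruction from named ingredients;
  the original procedure's details are unpublished, so agreement with it
  cannot be claimed — only that the implemented rule has the documented
  properties.
- Gene-level bootstrap is the only within-sample resampling unit available
  at test time; it treats genes as exchangeable within a signature, which
  underestimates uncertainty if signature genes are strongly correlated.
- The 4-gene HER2 bootstrap distribution is coarse (many replicates share
  few distinct multisets); flip fractions for HER2-involved pairs are
  correspondingly noisy.
- Thresholds fit on small or single-class cohorts fall back to pooled or
  quantile rules and should be treated as provisional; the decision and
  diagnostics are always recorded in the `ThresholdSet`.
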