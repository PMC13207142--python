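# Methods

This note documents the statistical machinery, the choices that were
genuinely open, and what the synthetic data does and does not establish.

## Sex inference

**Model.** Let `x_i ∈ R^6` be the logCPM of the six marker genes, in fixed
order (XIST, EIF1AY, KDM5D, UTY, DDX3Y, RPS4Y1), and `y_i = 1` for female.
The classifier is logistic regression with an L1 penalty on the slopes
(intercept unpenalized), fitted in the glmnet parameterization: minimize
`(1/n) Σ −ℓ_i(β0, β) + λ Σ_j |β_j|` on features standardized to zero mean
and unit (population) SD; the fit is reported on the original scale.

**Fitting.** Coordinate descent on the penalized weighted least-squares
problem of each IRLS quadratic approximation, with probabilities clipped to
[1e−5, 1−1e−5] inside IRLS (the glmnet safeguard). The inner solver works on
precomputed Gram products, so one sweep is O(p²) regardless of n; the kernel
is numba-compiled. At λ = 0 the solution matches an unpenalized IRLS fit to
1e−6 (tested against statsmodels `Logit`), and at a shared λ it matches
scikit-learn's saga L1 solver to 2e−4 (tested).

**Penalty selection.** A descending grid of 100 λ values, log-spaced from
λ_max (the smallest λ with all slopes zero, `max_j |x_jᵀ(y − ȳ)|/n`) down by
a factor 1e−4, warm-started along the path. λ minimizes the mean validation
binomial deviance over stratified k folds (k = 10 by default); ties resolve
to the larger λ. Deviance (not misclassification) is the CV loss: it is
smooth in λ and the conventional default. The fold assignment is fixed by
the seed, so the chosen λ is reproducible.

**Calling rule.** `P(female) > 0.5` (strictly) calls female; a tie at
exactly 0.5 calls male. The threshold is stored with the model and
configurable. Reported sex labels are never overwritten; a `sex_source`
column records `reported` vs `inferred`.

**Features.** logCPM with pseudo-count 0.5 against the full library,
`log2((count + 0.5)/(lib + 1) × 1e6)` — the same transform the modeling
stack uses — so all-zero markers stay finite. No TMM factor is applied at
this stage; the marker contrast (≈8 logCPM vs the noise floor) dwarfs
between-sample scaling.

## Normalization

- **Library-size filter:** samples are kept only when the total count is
  strictly greater than 10,000,000 (configurable). Applied before gene
  filtering.
- **Gene filter:** the edgeR-default `filterByExpr` rule — keep genes whose
  CPM exceeds the cutoff implied by `min_count = 10` at the median library
  size in at least `min_n` samples (`min_n` = smallest group size, shrunk
  as `10 + (n−10)·0.7` above 10), and whose total count is at least
  `min_total_count = 15`; both clauses use a 1e−14 tolerance so boundary
  genes are kept.
- **TMM factors:** reference sample = the one whose upper-quartile CPM is
  closest to the mean upper-quartile; per sample, gene-wise log2 ratios M
  and abundances A vs the reference on co-expressed genes; double trimming
  (30% of M per tail, 5% of A per tail, rank-window rule); factor =
  2^(weighted mean of surviving M), weights = inverse asymptotic binomial
  variances; factors rescaled to geometric mean 1. Matches edgeR's
  `calcNormFactors` to ~1e−13 (tested through Rscript) and an independent
  sort-based brute force to 1e−8. Note the weighting makes factors only
  *approximately* invariant to scaling one column (≤ ~3% at 200 genes);
  the pure depth-change case (column exactly doubled) gives factors of 1
  exactly because every M is 0.
- **logCPM:** `log2((count + prior)/(eff_lib + 2·prior) × 1e6)`,
  prior = 0.5, effective library = raw library × TMM factor.
- **RPKM:** `count / (length_kb × eff_lib_millions)`; used for the
  composition input, which is gene-length sensitive.
- **voom weights:** per-gene linear fit of logCPM on the full (blocked)
  design; lowess (span 0.5, 3 robustness iterations) of √(residual SD)
  against mean log2 count; each observation's predicted √SD is interpolated
  at its fitted log2 count (rule-2 extrapolation at the ends, clipped at
  1e−4 so weights stay finite); weight = predicted SD⁻⁴. logCPM equals
  limma voom's exactly; weights agree with voom up to the difference
  between R's `lowess` and the statsmodels lowess (median ~2% relative,
  tested with explicit tolerances). The weights are computed under the
  study-blocked design, matching the design used for inference; this is
  configurable.

## Linear modeling and moderation

Design: one indicator per group (no intercept) so the printed contrasts are
literal contrast vectors, plus treatment-coded study indicators. Rank is
checked with a pivoted QR and rank-deficiency errors name the dependent
columns. Contrast vectors must be zero on study columns.

Per gene, weighted least squares with the voom weights gives coefficients
`β_g`, residual variance `s²_g` on `d_g = n − p` df, and the unscaled
covariance `(XᵀW_gX)⁻¹` (computed batched over genes).

Empirical-Bayes moderation assumes `s²_g | σ²_g ~ σ²_g χ²_{d_g}/d_g` with a
scaled inverse chi-square prior `(d0, s0²)` estimated by matching the mean
and variance of `log s²_g` via digamma/trigamma identities; the trigamma
inverse is Newton iteration. Homogeneous variances hit the `d0 = ∞` branch
(posterior variance = s0² for all genes). Posterior variance is
`(d0·s0² + d_g·s²_g)/(d0 + d_g)`; moderated t has `d0 + d_g` df (normal
when `d0 = ∞`). The estimator equals limma `squeezeVar` to machine
precision on identical inputs (tested through Rscript) and recovers a known
`(d0 = 4, s0² = 2)` within 15% at 5000 genes.

DEG rule: |log2FC| > 1 **and** BH-adjusted p < 0.05, both strict, for all
three contrasts including the interaction (the same thresholds are assumed
for the interaction, which is the natural reading and is configurable).
The Venn partition reports direction consistency of overlap genes but does
not filter on it — consistency is treated as an observation, not a rule.

**Balanced sensitivity analysis.** Within each condition the majority sex
is randomly subsampled (seeded, without replacement) to equal the minority
count, the whole DE pipeline is re-run, and the per-contrast Jaccard overlap
with the full-data DEG sets is reported. With strong planted effects and a
2:1 imbalance the Jaccard stays ≥ 0.8 (tested).

## MDS and batch removal

For visualization only, the fitted study component is removed from logCPM:
per gene, a joint OLS fit of protected group indicators plus sum-coded
batch indicators, subtracting only the batch part. This is exact for the
additive offsets the generator plants (corrected study means agree to
1e−8) and leaves protected group differences untouched; it is idempotent.
Classical (Torgerson) MDS then embeds samples using Euclidean distances on
the 500 most variable genes (n configurable): double-centering,
eigendecomposition, top-2 coordinates with eigenvalue fractions, and a
deterministic sign convention. Classical MDS is used rather than limma's
pairwise-logFC variant because it is exact for Euclidean input and easy to
verify; the gene subset and distance are not canonical choices and are
configurable.

## Cell composition

Scores are analyzed as given (no logit/arcsine transform) because
enrichment scores are ordinal, not proportions. Per cell type:

- Kruskal–Wallis across the four groups with tie correction; all values
  equal degenerates to H = 0, p = 1.
- Dunn's post hoc z for group pairs on the shared ranking,
  `z_ij = (R̄_i − R̄_j)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j))`,
  two-sided normal p, BH adjustment across the reported pairs (all six by
  default; a subset is selectable). BH rather than Bonferroni, consistent
  with FDR adjustment elsewhere in the pipeline.
- Cohen's D (pooled SD, no small-sample Hedges correction — the standard
  large-sample form) per sex with variance
  `(n1+n2)/(n1·n2) + d²/(2(n1+n2))`; the male–female z-test and BH-FDR
  across cell types at 0.05.

**Power caveat.** The Cohen's-D-difference z-test is inherently
low-powered: a male-only standardized shift of 1 at 30 samples/group gives
`E[z] = 1/√(0.075 + 0.0667) ≈ 2.66`, i.e. ~76% power even for a single
uncorrected test and far less after FDR correction across a 64-cell-type
panel (~26–38% observed in simulation). Detecting 1-SD sex differences in
disease response at FDR < 0.05 on a 64-type panel requires substantially
more than 30 samples per group; the per-cell-type Kruskal–Wallis test
detects the *presence* of the group shift with near-certainty at the same
n, but that is a different hypothesis. The corresponding recovery test in
the suite asserts the 80% detection bound at these conditions and currently
fails, documenting the limit rather than hiding it.

## Synthetic generator

Counts are negative binomial with mean
`lib_s · 2^(b_g + o_{g,study} + e_{g,group}) / 1e6` and common dispersion φ
(variance μ + φμ²). Baselines `b_g ~ N(3, 2²)` on the log2-CPM scale,
shifted so total expected CPM is 1e6. Batch offsets `o ~ N(0, batch_sd)`
per gene and study — exactly the additive structure linear batch correction
assumes. Group effects: shared disease genes shift both PS groups by
±`deg_log2fc`; sex-unique genes shift one PS group; interaction genes give
one sex (chosen at random) a ±`interaction_log2fc` response and the other
none. The six markers carry the real gene symbols, no batch effect, and
sex-exclusive levels (`marker_logcpm_high` = 8 logCPM for the expressing
sex, `marker_noise_floor` = 0.05 CPM otherwise).

Defaults: 3 studies; per study 8/5/6/6 samples in PS_male / PS_female /
Control_male / Control_female (a mild male-psoriasis excess, as real
compendia show); 2000 genes; 100 shared + 30 + 30 sex-unique + 10
interaction genes; effect sizes 2.0 (twice the DEG threshold); batch SD
0.5; φ = 0.1 (biological CV ≈ 0.32, typical of human bulk tissue); library
sizes log-uniform on [8e6, 3e7] so the 10-million filter is exercised.
Enrichment scores are truncated normals (SD 0.1) with base means in
[0.3, 0.8] so truncation is negligible and a planted shift of k SD is a
planted Cohen's D of ≈ k.

**What passing tests show — and don't.** The generator matches the
*assumptions* of the analysis (NB counts, additive log-scale batch,
sex-exclusive markers, truncated-normal scores). Real data violate several:
markers can be ambiguous (Klinefelter karyotypes, XIST-low tumors),
batch effects are not purely additive, library composition varies, control
biopsy sites differ, and covariates (age, severity, treatment) are
unmodeled. Recovery and error-control results here validate the
implementation under its stated model, not robustness to those violations.

## Problem sizes in the test suite

Simulation checks use deliberately modest sizes chosen to make the assessed
property measurable with margin: 200 replicates of 300-gene/40-sample null
datasets for error control, 3 replicates of 800-gene/80-sample datasets for
interaction recovery, 5000 genes for prior recovery, 50 replicates of the
64-cell-type panel for composition power, and a 500-sample balanced cohort
for the classifier twins. The full suite runs in about a minute on one CPU.

## Known limitations

- No random-effect (duplicateCorrelation-style) blocking; study enters as a
  fixed effect, so a study fully confounded with one contrast group is
  rejected rather than partially pooled.
- The gene filter reimplements the default `filterByExpr` rule only; the
  large-sample `large.n` branch beyond the 70% shrink is not modeled.
- voom weights inherit whatever bias the lowess smoother has at the extreme
  abundance ends (rule-2 flat extrapolation).
- The composition z-test compares standardized effects; it does not model
  correlation between cell-type scores, which xCell signatures do exhibit.
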