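# Methods

This note documents the statistical models implemented in `mmuphin`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the methodology was
genuinely open.

## Batch correction

Non-zero counts are modelled as
`Y_ijp = exp{β_p′X_ij + σ_p(γ_ip + δ_ip ε_ijp)} · I_ijp` with batch *i*,
sample *j*, feature *p*; `I_ijp` is the zero indicator, `ε` standard
normal. Fitting proceeds per feature on the log of the non-zero entries:

1. **Standardization.** OLS of `log Y` on batch one-hot columns plus
   covariates (reference-coded categoricals, raw continuous). The
   batch-free grand mean `α_p` is the non-zero-count-weighted average of
   the batch-level coefficients (ComBat's batch-size-weighted sum-to-zero
   convention, with weights per feature because zero patterns differ).
   `σ_p` is the pooled residual SD (floor 1e-8). Standardized residuals
   `Z = (log Y − α_p − covariate fit)/σ_p` give frequentist `γ̂_ip`
   (batch mean) and `δ̂_ip` (batch SD, ddof=1, floor 1e-8).
2. **Empirical Bayes.** Per batch, a normal prior on γ (mean/variance
   across features) and an inverse-gamma prior on δ² (method of moments:
   shape `(V²+2S²)/S²`, rate `(V³+VS²)/S²` from the across-feature mean V
   and variance S² of δ̂²). Posterior means are computed by the standard
   iterative conditional updates until the largest change falls below
   1e-4 (cap 500 iterations). Degenerate across-feature spread (τ² or S²
   below 1e-12) short-circuits to the frequentist estimates; batches with
   fewer than 3 estimable features skip shrinkage with a warning.
3. **Correction.** For non-zero entries,
   `exp{(log Y − stand_mean − γ*σ)/δ* + stand_mean}`; zeros stay zero;
   each sample row is rescaled to its pre-correction total.

Batch-feature pairs with fewer than `min_nonzero = 2` non-zero
observations cannot support a location and scale estimate and are left
uncorrected (`γ* = 0, δ* = 1`); features with fewer than 2 non-zero
observations overall are left untouched entirely. Rank-deficient designs
(covariates confounded with batch) are refused with the offending columns
named, not silently dropped.

Two consequences are worth stating plainly. The correction never changes
presence/absence: a feature absent from one batch stays absent, because a
non-zero abundance cannot be imputed for an inflated zero. And the final
depth renormalization means batch differences in *total* counts are
treated as technical: the correction's guarantees hold on the
compositional (relative-abundance) scale.

## Meta-analysis of differential abundance

Per study: total-sum scaling, arcsin-square-root transform, then OLS of
each feature on intercept + exposure + covariates. Rows with missing
exposure or covariate values are dropped (the `"missing"` level is never
imputed). If a subject column is given and any subject has repeated
samples, a random-intercept linear mixed model (REML, statsmodels
`MixedLM`) replaces OLS. Features entirely absent in a study, or studies
where the exposure does not vary, contribute no effect — an explicit
absence, not a zero.

Pooling per feature follows `β̂_ip = β_p + ε_ip + e_ip`. Fixed-effects
pooling is the inverse-variance mean. Random-effects τ² is the REML
estimate, computed by bounded scalar maximization of the restricted
log-likelihood (profiled mean), which is robust for the small study counts
typical of microbiome meta-analysis; it is validated in the tests against
a dense likelihood grid at 1e-4. Weights are `1/(se² + τ²)`; p-values are
two-sided normal (no Knapp–Hartung adjustment). BH FDR is applied across
features per exposure.

Moderator models regress per-stratum effects on a binary stratum indicator
by weighted meta-regression with random stratum effects (τ² again REML,
profiled over both coefficients); the indicator coefficient is the
interaction effect. Ordered three-level contrasts (e.g. disease-severity
classes L1 < L2 < L3) fit L2-vs-L1 and L3-vs-L1 on the corresponding
subsets plus a joint model with indicators I{L2 or L3} and I{L3}; the
incremental-L3 coefficient's FDR is computed only across features already
significant in either pairwise contrast, mirroring how severity gradients
are reported in practice.

## Discrete structure

PAM is implemented directly (BUILD initialization by greedy gain, then a
full SWAP phase with vectorized exchange evaluation); all ties break
toward the lowest sample index, so results are deterministic given the
dissimilarity matrix. When every candidate assignment ties (degenerate
all-equal dissimilarities), each medoid anchors its own cluster so no
cluster is empty.

Prediction strength splits samples at random into equal train/validation
halves (20 splits by default — both the fraction and the count are
conventions, configurable), clusters each half by PAM, classifies
validation samples to the nearest training medoid, and takes the minimum
over validation clusters of the fraction of intra-cluster ordered pairs
co-classified. Validation clusters of size 1 have no pairs and contribute
1. `ps(1) = 1` by definition; the selected cluster number is the argmax of
average prediction strength over k ≥ 2 (ties to the smaller k).
Generalized prediction strength applies the same score across studies:
cluster each study separately, classify study i′'s samples to study i's
medoids, and average over validation studies i′ ≠ i.

Supported dissimilarities: Bray-Curtis, binary Jaccard, and root
Jensen-Shannon divergence (natural log, 0·log 0 = 0, rows re-closed).
Quality indices: average silhouette width from the dissimilarity matrix
and Calinski-Harabasz from the feature-space data.

## Continuous structure

Per study: center the arcsin-sqrt-transformed relative abundances
per feature, SVD, keep the smallest set of top loadings whose cumulative
variance explained reaches `threshold_v` (default 0.80). Across studies,
loadings are aligned by feature-ID intersection (restricted vectors
re-normalized; the dropped fraction is reported), and every cross-study
pair with `|cos| > threshold_s` (default 0.7) becomes a weighted edge.
Modules come from deterministic greedy (Clauset–Newman–Moore) modularity
maximization on edge weights; singletons are discarded and modules are
ordered by size, then mean internal edge weight. Within a module, the
first member in (study, PC) lexicographic order anchors the sign; others
flip to positive cosine with it, and if any pairwise cosine remains
non-positive the module is rejected as sign-inconsistent with a pointer to
raise `threshold_s`. The consensus loading is the plain average of the
corrected members (not re-normalized, matching the defining formula; a
unit-norm variant sits behind a flag — scores are scale-equivalent, so
ranks and correlations are unaffected either way). A study may contribute
two PCs to one module; both are kept and averaged. Scores are
`centered transformed profile · W_k`; external validation takes the
maximum |cosine| between W_k and a validation study's top three PCs
against the same `threshold_s`.

## The simulator

Null profiles are `Y_ip ~ LogN(μ_p, σ²_p) · Bernoulli(π_p)`, independent
across features and samples. The packaged default parameter set (one fixed
set per feature count, internal seed) mimics a stool-like genus table:
log-abundance locations spread with SD 1.5 (clipped at ±2.7) so a few
taxa dominate a long tail, log-SDs uniform on (0.5, 2), prevalence rising
with abundance through a logistic link (dominant taxa near-core, rare taxa
heavily zero-inflated; mean prevalence ≈ 0.2), and locations offset to an
expected sample depth of ~3×10⁴. Because the original training data for
the published null fit is external, the free spread/prevalence constants
were fixed once so that the package's reference design (8 batches × 500
samples, 200 features, 10% spiked at strength 10) reproduces the published
community-level effect magnitudes for that design (~10% batch R², ~3%
binary-exposure R²); `fit_null_model` refits all three parameter vectors
on any user table.

Associations are spiked by
`Ỹ = (Y + φ[(X−μ_X)σ_Y/σ_X + μ_Y])/(1+φ)`, which preserves the feature's
mean and approximately its variance while tying it to X with strength φ.
Two implementation choices matter:

* **Non-zero restriction (default).** The formula is applied to a
  feature's non-zero entries, with moments taken over those entries, and
  values driven negative are floored at the feature's smallest pre-spike
  positive value. The zero pattern is therefore preserved exactly, and
  spiked batch effects stay in the location/scale family the correction
  model addresses. Applying the formula to the full vector
  (`spike_zeros=True`) is also available: it matches the formula as
  written, truncates negatives to 0, and lets spiking create or destroy
  presence — but at φ = 10 a binary indicator then converts most of its
  minority group to absences, producing presence/absence batch effects
  that no location/scale correction can remove and community-level effect
  sizes several-fold above the published anchor, so it is not the default.
  The floor introduces a modest upward bias in the spiked feature's mean
  (the pre-floor formula is exactly mean-preserving); the number of
  entries that fell below zero is recorded in the truth record.
* **Categorical variables.** An L-level variable (batch, cluster label) is
  spiked through per-level binary indicators, each perturbing half the
  variable's feature budget `round(pct_spiked · P)` with its own random
  target subset; a binary variable's two complementary indicators collapse
  to a single indicator carrying the full budget. The halving reflects
  that each indicator contrasts one level against all others and keeps the
  multi-level and binary conventions consistent at L = 2; with the
  reference null parameters it reproduces the published batch-to-exposure
  R² ratio.

Scenario builders assemble the four evaluation designs: batch +
binary/continuous positive controls + untouched negative control;
study-confounded null (binary exposure with per-batch case fraction
0.5 ± imbalance/2, alternating enrichment across batches, associated with
no feature); planted discrete clusters (uniform labels independent of
batch); planted Uniform(−1, 1) gradient. Every generator is a pure
function of (parameters, seed).

What the simulator does **not** emulate: feature-feature correlation
(co-occurrence, phylogenetic structure), compositional closure during
generation (counts are independent before TSS), sequencing-depth
variation beyond the log-normal draw, longitudinal autocorrelation, and
multiplicative (log-scale) batch effects of the correction model's own
form. Passing the recovery benchmarks therefore shows the components work
under realistic marginals and controlled confounding — not that they are
robust to correlated or compositionally-generated communities.

## PERMANOVA harness

R² is the between-group share of the total sum of squared dissimilarities
(Gower partition): for categorical variables via group sums of D², for
continuous variables via the quadratic form `x_c′ G x_c / (x_c′x_c)` on
the double-centered matrix. Variables are tested marginally. String-typed
variables are always categorical; only genuinely numeric inputs take the
continuous path. P-values are permutation-based, `(count+1)/(n_perm+1)`
(never 0), default 2000 permutations, with three schemes: free,
within-block (per-sample variables under repeated measures), and
block-level (per-subject variables, whole blocks carried). Conditioning is
by sample subset before testing.

## Benchmarks and problem sizes

The packaged benchmarks run each published evaluation design at desk
scale: the PERMANOVA anchor at full size (8×500, 200 features, ≥5
replicates); FPR control at 2×100, 200 features, 20 replicates;
correction at 4×100, 1000 features, 20 replicates per batch-effect level;
discrete recovery at 2×250, 1000 features, true k = 3, 20 replicates;
continuous recovery at 4×100, 1000 features, 20 replicates. These sizes
keep the full validation suite within a few minutes on one CPU while
leaving each design's success criterion (FPR window, pre/post ordering,
recovery thresholds) clearly resolvable above Monte-Carlo noise.

## Known limitations

* Correction assumes batch effects act on the location/scale of log
  non-zero abundances; presence/absence batch effects pass through
  untouched (by design, but worth re-stating).
* REML τ² from 2–3 studies is noisy; the pooled test then leans toward
  conservatism (observed FPR ≈ 0.03 at nominal 0.05 in the two-study
  benchmark).
* Prediction strength needs tens of samples per cluster; the screening
  convention of ≥ 33 samples per study reflects that.
* The continuous-structure network treats PCs as the only loading
  candidates; gradients spread across many small-variance components are
  invisible.
* QC prevalence filtering applies the depth filter first, then
  per-study prevalence on relative abundances (the order is a documented
  assumption).
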