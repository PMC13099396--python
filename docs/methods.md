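# Methods

This note documents the statistical machinery implemented in `pexwas`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Estimation model

Every association is a weighted least squares fit of a standardized
quantitative phenotype on a transformed exposure plus scenario covariates.
Nine covariate scenarios are built in; the fully adjusted one uses age,
age² (age is centered at its survey-weighted mean before squaring, for
conditioning and shift-invariance), sex, income-to-poverty ratio, ethnicity
(5 levels), education (3 levels) and survey wave, with categorical
covariates expanded against their largest weighted category (ties broken
lexicographically). The wave indicator enters pooled fits only and is
dropped automatically from single-wave fits.

Transforms:

- **Phenotypes** are standardized to survey-weighted mean 0 / s.d. 1
  (denominator Σw − 1); a rank-based inverse-normal option (Blom scores,
  Φ⁻¹((rank − 3/8)/(n + 1/4)), ties mid-ranked) is provided.
- **Continuous exposures** are log₁₀-transformed and standardized. When
  zeros are present, a constant equal to the smallest nonzero observed
  value is added to *all* values before the log (a uniform shift preserves
  order; applying it only in the presence of zeros keeps zero-free
  exposures untouched). The offset, standardization moments and reference
  categories are computed on the **pooled cross-wave estimation sample** of
  the pair, so the transform is identical in every wave; a per-wave option
  exists. Values below an assay's limit of detection are substituted by
  LLOD/√2 before transformation, and the censored fraction is tracked per
  analyte and wave.
- **Ordinal exposures** enter as numeric rank codes; **categorical**
  exposures as indicator columns (one association record per non-reference
  level).

The estimation sample is the complete cases for the scenario's covariates;
the covariates-only model behind every incremental R² is refit on exactly
the full model's sample, so the R² difference is non-negative by nesting.

## Design-based variance

Weights: when a pair merges components measured on different subsamples,
the analysis weight is the one from the smallest subsample (it constrains
the estimation sample); pooling k waves divides the weight by k so pooled
estimates refer to a single-wave pseudo-population. Variances use Taylor
linearization: PSU totals of weighted score residuals are contrasted within
strata with the n_h/(n_h − 1) small-sample factor, and t inference uses
`#PSUs − #strata` design degrees of freedom (the conventional rule;
two-PSU-per-stratum public-use designs leave no obvious alternative).
Strata left with a single PSU after subsetting are scored against the grand
mean of all PSU totals (certainty-like handling), with a configuration
switch to raise instead. Weighted R² (1 − RSS_w/TSS_w about the weighted
mean) is reported; whether an unweighted R² was intended upstream is
unknowable from the outputs, so weighted is the documented default.

The linearized standard errors are validated in the test suite against a
from-first-principles sandwich oracle (exact agreement at 1e−10) and a
stratified delete-one-PSU jackknife (agreement within 15% on 30-PSU
designs; both estimators are design-consistent but not identical).

## Cross-wave pooling

Both cross-wave estimates are always produced: the pooled regression with
wave indicator (headline pathway) and per-wave fits combined by
unrestricted WLS — the inverse-variance fixed-effect estimate whose
standard error is multiplied by √(H²) = √(Q/(k−1)) with **no floor at 1**;
Q = 0 yields a zero standard error, flagged rather than truncated. The
UWLS p-value uses a t reference on k − 1 degrees of freedom (honest for
the small k of real survey series; a normal-reference switch exists). At
k = 2 this reference is extremely conservative — one of the reasons the
pooled-regression p is also carried and is the recommended selection
column for downstream modeling. Replication counts per association:
`model_concordance` = waves with p < 0.05, `model_concordance_1_2` = those
whose sign matches the pooled estimate, `replicated` = concordance ≥ 2.

## Multiplicity, inflation, power

Bonferroni and Benjamini–Yekutieli (step-up with c(m) = Σ 1/i, monotone,
capped at 1) are computed within each scenario family — one family of
tests per adjustment scenario, matching "across all tests" of a run.
Significance tiers are nested (Bonferroni ⊂ FDR). The exposome inflation
factor is λ = median(z²)/median(χ²₁) with |z| recovered from two-sided
p-values when statistics are not supplied. The power module inverts the
noncentral-F power function of a 1-df exposure test (noncentrality
n·R²/(1 − R²), denominator df n − 2) by bracketing; it reproduces the
conventional minimum-detectable-R² ladder (0.05 at n = 608; 0.004 at
n = 7,464; 0.002 at n = 15,316 for α = 10⁻⁶, power 0.80) and is
cross-checked by direct simulation.

## Poly-exposomic models

For one phenotype, exposures FDR-significant in the atlas are ranked by
univariate incremental R² (deterministic name tie-break) and truncated at
k_max = 20. Missing exposure values (subsample non-membership) are
completed by chained-equation imputation with predictive mean matching:
each incomplete column is regressed on all others, coefficients are
perturbed by a draw from their sampling distribution (σ² from its scaled
inverse-χ² posterior), and each missing case copies the observed value of
one of d = 5 nearest-prediction donors; 10 sweeps of burn-in, m = 10
imputed datasets, fully seed-reproducible. d = 5 and 10 sweeps are the
standard defaults of the chained-equations literature. Incremental R² over
the demographic baseline (age, age², sex, ethnicity, education — income is
deliberately not in this baseline, mirroring the four-covariate baseline
used for exposome-vs-genetics comparisons) is averaged over imputations;
coefficient tables are pooled by Rubin's rules. Fits are survey-weighted
by default with an unweighted switch.

## Exposure globes and shared architecture

Partial correlations residualize both transformed exposures on age, age²,
income, education and ethnicity via survey-weighted least squares and
correlate the weighted residuals (weighting applied throughout; an
unweighted switch exists since correlation weighting conventions vary),
with t-based p-values on n − #covariates − 2 df. Globe graphs keep edges
with |r| above a threshold (default 0.25), drop isolates unless asked
otherwise, and export to GraphML/CSV with catalog-driven node categories.
Shared associational architecture is the Pearson correlation of two
entities' association vectors across the opposite atlas axis,
pairwise-complete, undefined below 3 shared cells.

## Synthetic survey generator

The generator emulates the *structure* of a public-use health survey, not
its prevalences: per wave, S strata × 2 PSUs × n participants; full-sample
weights built as base weight × lognormal noise (dispersion 0.25) and
ratio-adjusted so each stratum sums to its share of a configurable
pseudo-population (default 10⁶); Bernoulli subsample panels whose weights
are full weight / panel fraction; log-normal exposure biomarkers with
left-censoring at a configurable LLOD quantile; categorical/ordinal
exposures cut from the latent score at quantiles. Demographics: age
N(45, 15²), sex Bernoulli(½), 5-level ethnicity and 3-level education with
fixed realistic frequencies, income-to-poverty 2.5 + 1.25·z with z
truncated-normal on [−2, 2] (kept linear in its driver so adjustment is
exact).

Every variable is a linear combination of an orthonormal factor basis
(standardized observed demographic drivers, block factors shared within
exposure groups, idiosyncratic terms, optional PSU effects, noise), so the
truth table — univariate and demographic-adjusted standardized slopes,
exposure-block incremental R², latent exposure correlations — is exact
linear algebra on the loading matrix. Configurations whose demographic
loadings plus block correlation exceed unit variance are rejected as
non-positive-semidefinite.

What the generator does **not** emulate: real assay error structure,
informative (non-Bernoulli) subsample selection, oversampling-driven
weight–outcome correlation, item nonresponse outside exposure panels, and
non-normal phenotype tails. Passing the calibration suites therefore
demonstrates correctness of the estimation machinery under a faithful
design *structure*, not robustness to every pathology of real survey data.

## Validation studies and problem sizes

The test suite runs entirely on generated data, sized to finish in minutes
on one CPU:

- **Null calibration**: four independent populations × 500 null pairs
  (25 phenotypes × 20 exposures, 2 waves, n ≈ 3,000/pair). Type-I error at
  α = 0.05 is checked on one population's 500 pairs (tolerance ±0.015);
  the inflation factor is computed over all ~6,000 pooled and per-wave
  p-values because the Monte-Carlo error of a 500-test median (~0.10)
  would be comparable to its ±0.1 tolerance; the median I² across
  homogeneous waves is checked to be ≈ 0.
- **Recovery**: a planted standardized effect of 0.2 at n ≈ 5,000 per wave
  must lie within 3 linearized SEs of its analytic truth, with 95% CI
  coverage ≥ 90/100 replicates; an aggregate five-exposure R² of 0.30 with
  25% panel missingness must be recovered within ±0.05 through the full
  selection → PMM → joint-fit flow.
- **Oracles**: sandwich and jackknife variance oracles, statsmodels'
  BH/BY step-ups, closed-form UWLS and Blom-score examples, and a
  10,000-replicate power simulation at the inverted R².

Seeds are fixed (0 unless a test needs distinct streams), making every
stochastic check deterministic.

## Known limitations

- Only continuous phenotypes; no generalized linear families, no
  binary/ordinal outcomes, no mediation.
- No replicate-weight (BRR/Fay) variance engine; the jackknife exists only
  as a test oracle.
- The UWLS k−1-df reference is conservative at k = 2; users pooling two
  waves should prefer the pooled-regression p-value, as the poly-exposome
  selection does.
- LLOD substitution at LLOD/√2 biases standardized slopes slightly toward
  zero at high censoring fractions; the generator defaults keep censoring
  ≤ 10% and recovery tests use uncensored exposures.
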