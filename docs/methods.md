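# Methods

This note documents the statistical models implemented in `fcselect`, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## Connectivity features

Per subject, cleaned BOLD series for 106 atlas labels are grouped into 17
meta-analytic regions (the shipped YAML map; regions appearing in both
directions of the source contrast — right cingulate, left insula — are
listed once). Aggregation is the unweighted mean of a region's label series
at each timepoint, computed *before* correlating; the alternative —
correlate at label level, then average the Fisher-z values over each region
pair's label pairs — is available via
`connectivity_features(..., aggregate=False)`. Mean-then-correlate is the
default because it is the conventional construction for region-level
connectivity and yields the compact 17·16/2 = 136-edge predictor block.

Correlations are plain Pearson on the supplied series (any detrending or
filtering is assumed done upstream). Fisher's z = arctanh(r) is applied with
|r| clamped to 1 − 1e−7: degenerate finite-sample series can reach |r| = 1
exactly, and a clamped large-but-finite z is more useful downstream than an
error. Edge order is fixed to the upper triangle in region-map order, so
feature tables are bit-reproducible.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the motivating community study: 569 subjects, 400-volume
scans, 16 self-report measures, and the 136 region edges.

- **Time series.** Each region has a latent stationary Gaussian AR(1)
  signal (autoregression 0.4 by default — of the order of cleaned,
  band-passed BOLD at short TR); the latent signals have a specified
  cross-region correlation matrix. Each atlas label mixes its region's
  signal (variance fraction 0.7) with independent AR(1) label noise.
  Aggregated region series therefore recover the target inter-region
  correlations up to a known mild attenuation (factor f/(f+(1−f)/L) for a
  region with L labels at signal fraction f ≈ 0.93 at f = 0.7, L = 6).
- **Self-report measures.** A latent Gaussian copula with a specified
  correlation matrix; continuous margins are affine transforms (clipped to
  instrument ranges), binary margins threshold the latent at the quantile
  matching the target rate, and heavily right-skewed measures (physical
  activity) use a lognormal matched to the target mean and sd. Default
  margins follow the published descriptives of the emulated study; default
  inter-correlations are moderate, hand-set values (impulsivity facets
  0.25–0.55, depression–negative affect 0.5, depression–sleep 0.4, …)
  shrunk toward identity just enough to guarantee positive definiteness.
- **Outcome.** y = intercept + X_std·β + N(0, σ_noise), with X_std the
  column-standardized full design — the same linear model the selection
  stage assumes. The default sparse β places six effects (0.31–0.46 in
  magnitude, matching the model-averaged coefficients the emulated study
  reports) on five self-report measures and one frontal-frontal edge;
  σ_noise = 2.8 reproduces the study's outcome spread (observed synthetic
  outcome mean ≈ 3.1, sd ≈ 3.1 against the study's 2.98 / 3.02). The
  outcome is generated Gaussian because the analysis model is an ordinary
  linear regression; `outcome_family="count"` rounds and clips to the
  instrument range [0, 17] for robustness checks.
- **Missingness.** Per-variable MCAR rates derived from the study's
  per-measure case counts (0.35–7%), plus the by-design rule: the
  depression variable is deleted for every subject older than 65. Age is
  normal (43.5, 18.4) clipped to [18, 85], which yields ~12–14% of subjects
  over 65. Demographics are always complete.

What the generator does **not** emulate: raw BOLD volumes, head motion,
scanner noise, item-level questionnaire responses, non-Gaussian FC tails,
and missingness that depends on unobserved values (MNAR). Passing tests on
this cohort therefore demonstrate correctness of the pipeline under its own
assumptions — linear signal, Gaussian copula predictors, MCAR-plus-by-design
missingness — not robustness to violations of them.

## Multiple imputation

Fully conditional specification with proper Bayesian draws, the standard
"norm"/"logreg" pair:

- Continuous: ordinary least squares on the observed rows of the target
  given all other columns, then σ² drawn as RSS/χ²(df), coefficients drawn
  from N(β̂, σ²(ZᵀZ)⁻¹), and missing entries predicted with added N(0, σ²)
  noise.
- Binary: maximum-likelihood logistic fit, a coefficient draw from the
  asymptotic normal approximation, then Bernoulli sampling; if the fit
  fails (separation, singular covariance) the variable falls back to
  observed-marginal draws with a logged warning.
- Heavily skewed variables can be imputed on a log1p scale and
  back-transformed (non-negativity enforced).

Missing entries are initialized by draws from the observed marginals; the
roster is cycled in fixed order for `fcs_cycles` sweeps (default 20 — a
conventional FCS burn-in, since each variable's conditional model is refit
every sweep). Stream i uses seed `seed + i`, so observed cells are
bit-identical across imputations and the whole set is reproducible. The
outcome is included as a predictor in every conditional model by default;
excluding it biases predictor–outcome associations toward null. FC edges
are treated as always complete (scan-level exclusions remove whole
subjects, not edges). Imputation-model designs must have fewer columns than
observed rows; perfectly collinear designs raise an error naming the
columns.

The per-variable mean (over missing cells) of the across-imputation
variance is reported: it must be positive for any properly imputed
variable — a single-value fill would be detected immediately.

## Spike-and-slab selection

The continuous spike-and-slab ("SSVS") model and its Gibbs sampler are
described in the README. Numerical and design choices:

- **Joint β update.** β is drawn in one multivariate-normal block per
  iteration via Cholesky of the conditional precision XᵀX/σ² + D_γ⁻¹.
  Component-wise β updates mix poorly under correlated predictors; the
  joint draw also remains valid for p > n (a warning notes that results are
  prior-dominated there).
- **Spike and slab scales.** Defaults τ₀ = 0.02, τ₁ = 0.5 on the
  standardized-predictor scale (ratio 25). The ratio is the critical
  tuning: the γ_j update odds are π·N(β_j; 0, τ₁²)/((1−π)·N(β_j; 0, τ₀²)),
  and with a very small spike (ratio ≳ several hundred) an included
  coefficient of typical posterior spread ~σ/√n almost never re-enters the
  spike, so the indicator chain's flip rates collapse to ~10⁻²–10⁻³ per
  iteration and MIP estimates at a 20,000-iteration run carry Monte-Carlo
  errors of ±0.05–0.10. At ratio 25 — inside the classic recommendation of
  10–100 for continuous spike-and-slab priors — "excluded" coefficients are
  still below ~0.06 on the standardized scale while indicator flips occur
  every few iterations; measured worst-case disagreement with exact
  enumeration is ≈ 0.02 at the default run length. A semi-automatic slab
  (`slab_sd="auto"`, max(0.5, 2·sd of ridge coefficients)) is available for
  outcomes on unusual scales.
- **MIP estimator.** Rao-Blackwellized: the average over kept iterations of
  P(γ_j = 1 | β_j) rather than of the binary draws — identical expectation,
  strictly smaller Monte-Carlo variance, and exact (zero-variance) in the
  degenerate τ₀ = τ₁ diagnostic configuration, where the MIP equals the
  prior π.
- **Intercept.** Handled by centering y (equivalent under standardized
  predictors, and one fewer parameter to sample).
- **σ² prior.** IG(0.01, 0.01), weakly informative; both shape and scale
  are configurable for sensitivity reruns (e.g. IG(1, 1)).
- **Reported coefficients.** `avg_beta` averages all β draws — spike draws
  included, realizing model averaging over zero and non-zero states — and a
  clearly separated `conditional_beta` averages only over draws with
  γ_j = 1.
- **Diagnostics.** Per-indicator effective sample size from an
  FFT-autocovariance initial-positive-sequence estimator; optional
  multi-chain runs report a between/within R-hat on inclusion frequencies.

### Exact enumeration oracle

For p ≤ 15 the posterior over all 2^p inclusion patterns is computed
directly: given γ, y is zero-mean Gaussian with covariance
σ²I + X D_γ Xᵀ, evaluated through the Woodbury/determinant identities on
the p × p scale; σ² is integrated against its inverse-gamma prior by
adaptive quadrature on log σ² (an 81-point pilot grid locates the
integrand's mode and sets the stabilizing offset; `scipy.integrate.quad`
then refines, and non-convergence is an error, not a warning). Pattern
weights combine these marginals with the Bernoulli(π) prior via
log-sum-exp. The oracle shares nothing with the sampler beyond the design
matrix, so agreement between the two is a genuine cross-validation of both.

## Pooling, cutoff, and model comparison

Pooled MIPs and coefficients are arithmetic means across the m imputations
(a logit-scale mean was considered and rejected as the default: MIPs of 0
and 1 occur routinely and would need ad-hoc clipping). The sampler seed for
imputation i is `seed + i`, recorded in the manifest. Selection uses a
fixed default cutoff of 0.5 with ties included, and predictors within 0.05
below the cutoff are flagged as near-threshold rather than silently
dropped; `mip_plot_data` provides the descending-MIP table with
consecutive gaps for the graphical elbow inspection that motivates
per-outcome cutoffs. The with/without-covariate comparison aligns rosters
that may differ only by the covariate and classifies each predictor as
retained, dropped, newly selected, or unselected.

## Problem sizes in the shipped analyses

The `analysis/` drivers run the study-scale cohort (n = 569, 152 candidate
predictors) with m = 10 imputations and 4,000-iteration chains (1,000
burn-in) per imputation; these sizes make each driver a matter of seconds
to a quarter-minute while leaving all statistical structure intact, and
every size is a single constant at the top of the driver. The acceptance
script similarly uses 5 oracle instances, 5 recovery replicates, 3
null-calibration cohorts, and an m = 10 end-to-end run. The test suite
uses the full default run length (20,000/5,000) wherever a check is about
sampler accuracy itself.

## Known limitations

- MIPs of strongly correlated predictors dilute across the correlated set;
  in low signal-to-noise regimes the selection includes correlated proxies
  of true effects with diffuse MIPs (visible in the study-scale driver).
  This is a property of model-averaged selection, not of the
  implementation; the across-imputation `mip_sd` and the MIP-gap table are
  the provided diagnostics.
- The FCS engine fits unpenalized conditional models: it requires fewer
  predictor columns than observed rows and offers no multilevel or
  interaction-preserving imputation.
- The enumeration oracle is exponential in p by construction and refuses
  p > 15.
- Binary-variable imputation uses an asymptotic posterior approximation,
  not an exact Bayesian logistic draw.
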