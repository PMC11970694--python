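# Methods

## The question and the quantities

Populations whose children are measured against an external growth standard
often show a steep decline in mean height-for-age z-scores (HAZ) over the
first 24 months. Two explanations compete: growth faltering (environmental)
and canalization toward the genetically expected height channel. The
package's core quantity is the per-child discrepancy

```
D = HAZ − THz
```

where THz is the target-height z-score: the sex-corrected mid-parental
height `TH = (F + M ± d)/2` expressed in SD units of an adult reference at
228 months by the child's sex. Under pure canalization, D starts positive
at birth (children are born long relative to their channel) and converges
to zero; under faltering, D keeps falling with age. Cross-sectional cohorts
cannot follow individuals, so D is read as a population trajectory: its
age profile, smoothed by LOWESS and summarized in 3-month bins.

## z-scoring conventions

* LMS transform computed via `expm1`/`log1p` so the `L → 0` limit is exact
  to machine precision; the inverse transform round-trips to ~1e−13.
* LMS parameters are stored as monthly rows per sex and interpolated
  linearly in age, each of L, M, S independently. How the original Stata
  tooling interpolates between tabulated ages is not documented anywhere we
  could verify; plain linear interpolation (including through sign changes
  of L) is this package's choice.
* Measurement position: recumbent under 24 months, standing from 24 months.
  A measurement taken in the non-conforming position is corrected by the
  conventional 0.7 cm and relabelled, making the correction idempotent. The
  correction is switchable off (`adjust=False` / `adjust_measurement:
  false`).
* Outliers: z strictly below −4 or strictly above +4 are flagged and
  excluded from analysis; the boundaries ±4 are retained (literal reading
  of the rule "less than −4 and over +4").
* BAZ uses the plain LMS transform with BMI computed from the mode-adjusted
  height; no extreme-value rescaling of weight-based indicators is applied
  (a documented limitation — the ±4 filter removes the far tails anyway).
  Nutritional status: underweight (BAZ < −2), normal (−2 ≤ BAZ < 2),
  overweight–obese (BAZ ≥ 2).

## Target heights

`d` is the mean father−mother height difference, estimated per survey wave
from the analysis sample by default (a fixed `d` — e.g. the rounded 11 cm
sometimes quoted — is available as a config override). Parents outside a
plausibility window (default 120–210 cm) are excluded from `d` estimation
and their children get missing target heights; counts are logged, never
silently dropped. THz is evaluated at exactly 228 months. The alternative
THz definition — the mean of the two parental z-scores — is provided as
`thz_from_parental_haz` but is not used by the pipeline stages. THz
subgroups follow the half-open bins (−∞,−3), [−3,−2), [−2,−1), [−1,∞).

## LOWESS

Written from scratch because the windowing is load-bearing: for each
evaluation point the ⌈bandwidth·n⌉ nearest neighbours by age form the
window, `h` is the window radius, tricube weights `(1−(|x−x₀|/h)³)³` feed a
weighted local *linear* fit evaluated at `x₀`; optional bisquare robustness
iterations. Degenerate windows (all ages identical) fall back to the
weighted mean with a logged warning. Local linear fits reproduce straight
lines and constants exactly, and the output is invariant to permuting the
input points. The evaluation grid is 121 evenly spaced ages over [0, 60]
months.

Two bandwidths appear in the package, deliberately:

* **0.8** is the default for descriptive smoothing, mirroring the default
  of the survey-analysis tooling the method is usually run with.
* **0.2** is used by the parameter-recovery checks that must resolve the
  24-month kink of the canalization curve. The choice is a bias–variance
  calibration on the generative model itself: smoothing a piecewise-linear
  curve with a kink biases the fit near the kink by ≈ 0.30·bandwidth·δ₀/1.5
  SD (measured on noiseless data), while the noise floor of the maximum
  smoothed value over ages ≥ 24 months shrinks roughly with the inverse
  square root of the window size. At n = 5000 and residual SD 1.0 the
  exceedance of a 0.1 SD bound is minimized near bandwidth 0.2. Even
  there the check is tight: typical maxima are 0.08–0.10, so single-seed
  runs sit close to the bound by construction.

Age bins are half-open `[a, a+3)` labelled `"a-b"`, matching the
"21–24 months" convention of the summaries the analysis mirrors. The
urban−rural gap uses a Welch-style normal CI,
`gap ± z₀.₉₇₅·√(s²ᵤ/nᵤ + s²ᵣ/nᵣ)` — standard for unequal-variance survey
strata; the source analysis does not state its CI method.

## Regressions and tests

OLS (statsmodels) with intercept, complete-case per model with dropped-row
counts logged; categorical predictors expand to indicator contrasts with
the first level as reference; rank-deficient designs raise an error naming
the collinear columns. Because "the correlation between THz and HAZ" is
ambiguous between a Pearson correlation and a standardized coefficient,
`thz_haz_association` reports both, per age group (0–<6, 6–<24, 24–<60
months). ANOVA is the classical between/within decomposition with explicit
degenerate handling (all values identical → not computable; zero
within-group variance with distinct means → F = ∞, p = 0); chi-square is
Pearson's without continuity correction. No survey weighting, clustering,
or multiplicity adjustment is applied — the analysis this package
implements uses none.

## The synthetic cohort generator

What it emulates: cross-sectional parent–child pairs over four survey waves
(identified by year: 1993, 2000, 2007, 2014) with

* per-wave parental height means/SDs reproducing the published survey
  summaries (fathers 161.50→162.71 cm, mothers 150.21→151.20 cm), bivariate
  normal with correlation 0.2, truncated to 120–210 cm by redraw;
* a child latent z-score `z = THz + δ(age) ± urban_offset/2 + ε`,
  `ε ~ N(0, residual_sd²)`, with THz computed from the simulated parents by
  the same code path the analysis uses — the generating THz coefficient is
  therefore exactly 1;
* `δ(age) = δ₀·(1 − age/t_canal)` for `age < t_canal`, else 0, defaults
  δ₀ = 1.5 SD and t_canal = 24 months (the two printed anchors of the
  observed trajectory). The linear shape is the simplest curve through the
  anchors; the true shape is not identifiable from published material, so
  `simulate_cohort` accepts any `delta_fn(age)` as an override;
* raw heights via the inverse LMS transform plus N(0, 0.3 cm) instrument
  noise; measurement mode consistent with age; weights derived from a BAZ
  draw N(−0.2, 1.2²) through the BMI reference;
* covariates with survey-like marginals (per-wave food-expenditure share,
  parental basic-education rates, Java–Bali share; boys 51.2%, urban 50%,
  ages uniform on [0, 60) for even bin coverage) and zero effect on height
  by default; effects can be switched on via `covariate_effects`;
* an optional `subgroup_pull` (off by default) adding regression toward the
  wave-mean THz, which reproduces the observed pattern that children of
  shorter parents overshoot their target the most.

The urban–rural contrast is parameterized by a single gap applied
symmetrically (+gap/2 urban, −gap/2 rural). An asymmetric offset would move
the pooled trajectory off its stated anchors; the symmetric form keeps the
pooled curve anchored at δ₀ and 0 while rural children dip below zero at
2–3 years, matching the qualitative survey pattern. The measured
urban−rural gap equals the parameter either way.

**Toy references.** Tests and simulations use closed-form tables: a child
standard linear in age (49.9 cm + 1 cm/month, L = 1, S = 0.04), a flat BMI
table (M = 16, L = −1, S = 0.1), and an adult anchor at 170/158 cm
(men/women, L = 1, S = 0.04). The anchor placement is a real design
decision: it spreads THz over several subgroups (mean ≈ −1.25, SD ≈ 0.57)
while keeping the whole simulated population inside the ±4 band, so the
gross-error filter stays near-inactive on synthetic data — which contains
no gross errors. Anchors that push the population mean to −2 SD (as real
surveys against an external standard do) make the ±4 filter structurally
truncate the lower HAZ tail, biasing the post-24-month discrepancy upward
by 0.1–0.2 SD and attenuating the THz coefficient to ≈ 0.87; that
truncation is a property of measuring a shifted population against an
external standard, not of the canalization model, and the toy anchor is
chosen to keep the two phenomena separate.

What the generator does **not** emulate: household clustering, sampling
weights, attrition, survey-realistic age pyramids, true longitudinal
trajectories, or the real marginal HAZ distribution against official
references. Passing recovery tests therefore demonstrates that the
pipeline's arithmetic and inference recover known generating parameters;
they do not validate the substantive claim on real survey data.

## Problem sizes and determinism

Recovery checks use cohorts of 4 × 1250 (the scale at which the birth-bin
mean has SE ≈ 0.065 SD) or 4 × 5000 (gap and coefficient recovery,
secular-trend monotonicity); the CI-coverage property uses 2000 simulated
null replicates of 50 + 50 observations. Every stochastic step flows from a
single integer seed through one `numpy` Generator; identical config + seed
gives a bit-identical cohort, and the analysis stages are seed-free.

## Known limitations

* Linear L-interpolation through sign changes and the exact ±4/±2 boundary
  conventions are literal readings; other tools may differ in the last
  decimal.
* The canalization curve's shape between the anchors is an assumption.
* BAZ omits the restricted-application rescaling some references apply to
  weight-based indicators beyond ±3 SD.
* `fit_ols` is complete-case; no imputation.
* The CLI's `zscore` stage flags out-of-range ages rather than failing, so
  downstream stages must (and do) filter on `age_in_range`.
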