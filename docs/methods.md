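# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `neuroage`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not itself measure.

## The unbiased brain-age model

The core estimand is the brain-age gap (BAG) `delta = Y_B - Y`: the
difference between the age a regression model reads off a participant's
imaging-derived phenotypes (IDPs) and their chronological age. Raw gaps from
any regression are negatively correlated with age (regression to the mean),
so we apply a post-hoc orthogonalisation: the raw gap is regressed on an age
basis and the fitted part removed. We use the quadratic basis `[1, Y, Y^2]`
by default — the cited bias-correction literature recommends allowing
curvature — with a linear basis available via `bias_basis="linear"`. The
corrected training gap is an OLS residual, so its correlation with `Y` and
`Y^2` is zero at machine precision (asserted at `1e-10` in the tests; this is
a construction guarantee, not an empirical finding).

Pipeline order and contracts:

1. **Deconfounding.** IDPs are residualised on `[1, C]` using weights
   estimated on training rows. Unseen data are residualised with the
   *training* weights; nothing is refitted on test data. Confounds must not
   contain age-derived columns, otherwise the age signal itself would be
   removed. A rank-deficient confound matrix falls back to the pseudo-inverse
   with a warning.
2. **Standardisation.** Per-feature z-scoring with training mean/SD. The
   source data mix units (volumes, thicknesses, diffusivities); an SVD on
   unstandardised features would be dominated by scale. Constant features get
   unit SD so they pass through harmlessly.
3. **SVD.** Top `k = 50` right singular vectors. `k` above the numerical rank
   raises with the achievable rank in the message.
4. **Age regression and bias correction** as above.

**Bias correction on unseen data** evaluates the training-fitted quadratic at
the new subject's age. The alternative — refitting the correction on the test
sample — forces exact orthogonality in the test set at the price of using
test-set information; it is implemented behind `refit_bias=True` and off by
default. With training-weights-only correction, the unseen-data |corr(delta,
age)| is bounded by sampling noise (~`2/sqrt(n)`), not by machine precision;
the acceptance script reports the realised value.

**Cross-validation.** 20 folds, 100 repetitions with random fold assignment
(both configurable; fold assignment is stratified by age decile by default so
every training fold spans the age range — plain random assignment is a flag).
Every fold refits the entire chain. Pearson r and MAE are computed on the
pooled out-of-fold *raw* predictions per repetition, then averaged across
repetitions. Raw (pre-correction) predictions are the right object here:
corrected predictions contain the subject's own age through the correction
term, which would inflate r spuriously — this is also why the no-leakage
null test checks raw out-of-fold correlations.

**Stratification.** Separate models per (sex, tissue); rows never mix across
strata, and records carry their stratum labels. Group-level analyses pool the
per-stratum gaps within tissue.

## Longitudinal quantities

`R_BAG = (delta_t2 - delta_t1)/dT` in years of BAG per year; display
conversions use 12 months/year and 365.25 days/year (so "months and days"
clock renderings are derived, display-only values: whole months floored from
`12*|v|`, remainder times 365.25/12 rounded to days). Age effects are
estimated by OLS of `R_BAG` on `AvgAge = (Age_t1 + Age_t2)/2`, the
interval-robust regressor for two-point designs; slopes are reported in both
y/y-per-year and days/year. The regressions are unadjusted by default, with a
sex covariate behind a flag.

Scan-rescan stability of predicted brain ages uses Pearson r, ICC(2,1)
(two-way random effects, absolute agreement, single measure — chosen because
the scientific claim is stability of the *same* quantity over time, which an
additive session offset should penalise; consistency ICC(3,1) is a flag) with
the McGraw–Wong F-based confidence interval, and a partial correlation that
residualises each session's prediction on that session's own age.

## Group statistics

- **Two-sample tests:** pooled-variance Student t by default (matching the
  convention of reporting Cohen's d with pooled SD); Welch via flag.
  Mann–Whitney uses exact enumeration for small tie-free samples
  (n1+n2 <= 20) and the tie-corrected normal approximation otherwise; an
  all-tied comparison returns p = 1.
- **FDR:** Benjamini–Hochberg step-up, one family per analysis panel (the
  family id is mandatory in outputs so users can re-pool).
- **Permutation ANOVA (2x2):** effect-coded linear model; for each effect the
  other terms are nuisance, reduced-model residuals are permuted
  (Freedman–Lane, the default of the permutation-inference toolboxes this
  re-implements; ter Braak — permute full-model residuals and recompute the
  statistic on them alone — behind a flag). F statistics per effect (for
  two-level factors any monotone equivalent gives the same permutation p);
  p-values use the add-one convention and are therefore never zero and valid
  by construction. With intercept-only nuisance the scheme reduces exactly to
  label permutation (verified against exhaustive enumeration).
- **Calibration:** empirical rejection rates under simulated nulls are judged
  against the package's own Wilson score interval — the same logic used to
  calibrate the permutation tests in the source analyses.
- **Deprivation stratification:** scores strictly above the 70th / below the
  30th percentile (linear-interpolation quantiles, strict inequalities,
  middle band unassigned). Indices are attainment-style: *low* = deprived.

## The synthetic cohort generator

No public generative model exists for this kind of cohort, so the generator
uses the simplest structure under which the (linear) pipeline's assumptions
hold, with magnitudes chosen once to resemble the published setting:

- **Ages** Gaussian (mean 62.6, SD 7.6) truncated to [45, 82] years.
- **True BAG**: a stable per-subject deviation `delta ~ N(0, bag_sd=3 y)`;
  "brain age" `b = age + delta` drives the IDPs.
- **IDPs**: `X = scores @ loadings + confound contamination + iid noise`,
  where the q = 10 component scores load linearly on standardised brain age
  plus a stable subject-level component (`component_noise_sd = 0.5`) that is
  identical across sessions. `signal_to_noise = 4` is the ratio of the
  age-driven signal SD to the measurement-noise SD; measurement noise is
  redrawn per session. These three dials decompose "noise" into stable
  individual structure vs. session noise; the noise-free limit (all three
  zero) makes prediction exact, which the tests exercise.
- **Longitudinal truth**: per-subject true rate = baseline drift (0.10 y/y)
  + 0.00821 y/y per year of average age (~3 days/year, the control-group
  age effect) + the injected exposure offset (`true_rbag_effect = 0.458 y/y`)
  + an extra offset for deprived exposed participants (0.2 y/y) + N(0, 0.7)
  subject noise. The second-session IDPs encode `delta_t2 = delta_t1 +
  rate * dT` exactly, and a `GroundTruth` table records every realised value.
- **Intervals and dates**: controls are scanned twice pre-onset with a narrow
  interval around 2.25 y; the exposed arm straddles the onset date
  (2020-03-01, configurable) with intervals uniform on [1.0, 4.5] y — mean
  ~33 months and roughly the stated share below the 2-year follow-up cut.
- **Cognition**: timed-test scores (seconds), follow-up = baseline x
  (1 + [drift + coupling x true rate x infected]/100 + noise); the coupling
  (10 %-points per y/y) applies only to the infected subgroup, matching the
  infected-only association the pipeline is meant to detect.
- **Seeding**: one master seed; each stage draws from
  `SeedSequence(seed, spawn_key=(stage_index,))`, so stages regenerate
  independently and identical configs reproduce byte-identical tables. A
  `replicate` integer extends the spawn key for fresh cohort draws under
  fixed generative loadings.

What the generator does *not* emulate: realistic inter-regional IDP
covariance (loadings are random Gaussian, not anatomical), disease phenotype
codes (eligibility is a boolean flag), scanner/site structure, non-Gaussian
score distributions, and informative missingness. Passing recovery tests
therefore show the *estimator* is correct under the stated assumptions, not
that real cohorts satisfy those assumptions.

## Numerical choices and conventions

- Outlier rule: |cell - column mean| > 5 sample SDs, per session; zero
  -variance columns flag nothing; any flagged cell excludes the
  participant-session (fraction-threshold policy available).
- Interval filter: drop rows strictly below the 10th-percentile interval or
  strictly below 2.0 years; ties at thresholds are retained. Because the
  percentile is recomputed on whatever sample it is given, re-application can
  remove further rows; the absolute `min_years` component is idempotent and
  is the one the re-application guarantee covers.
- Group assignment: both scans pre-onset = control; exactly one post-onset =
  exposed (split by infection status); both post-onset is outside the design
  and dropped with a logged reason.
- Balance: standardised mean difference with pooled SD (|SMD| > 0.1 flagged),
  t or chi-square p per covariate. Matching (greedy nearest-neighbour with
  caliper) is opt-in; achieved balance, not a particular matcher, is the
  contract.
- Orthogonality assertions at `1e-10` on standardised data; permutation p
  add-one convention; Fisher-z 95% CI on Pearson r.
- Missing IDP cells are not imputed; the participant-session is dropped.

## Problem sizes

Defaults are desk-scale choices: 1500 training participants, 200 IDPs per
tissue, 10 signal components, 400 per longitudinal group, 20-fold CV. The
acceptance script runs CV with 10 repetitions per stratum and 2000
permutations per 2x2 test; the test suite's null-calibration checks use 100
CV repetitions over 10 independent pure-noise datasets (n=500, M=200, k=50)
and 1000 replicate datasets at 1000 permutations. All sizes are configurable.

## Known limitations

- **Regression dilution.** A linear brain-age model recovers individual BAG
  deviations attenuated by the slope of the age regression on true brain age
  (about `var(age)/(var(age)+bag_sd^2)` ~ 0.87 at the defaults, slightly less
  with measurement noise). Group differences in BAG rates are attenuated by
  the same factor, so recovered effects sit a little below the injected
  value — within two standard errors at n = 400/group, as the acceptance
  suite verifies, but not unbiased. This is a property of the estimator
  class, not of the implementation.
- The two-point rate `R_BAG` cannot separate within-subject trajectory shape
  from measurement error; no mixed-effects trajectory model is provided.
- The partial-correlation p-values use the Pearson p of the residualised
  variables without degrees-of-freedom adjustment for the residualisation
  (one covariate; the difference is negligible at the n used here).
- ICC confidence intervals assume the two-way ANOVA normal model.
- The sliding-window cognition curves are descriptive; no changepoint or
  threshold model is fitted.
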