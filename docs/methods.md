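# Methods

## Scoring model

Each respondent is classified on six binary successful-aging dimensions.
Thresholds are *cohort-relative*: apart from the disease criterion (a fixed
morbidity-code set applied identically in both cohorts), every cutoff is
defined within cohort, acknowledging normal age-related decline between two
cohorts twenty years apart and different engagement opportunities before and
after retirement.

**Disease.** A respondent is disease-free when no morbidity code falls in
the qualifying ranges `0400-0540 (excluding 0455), 0720, 1000, 1015-1030,
1205, 1315, 1940-1950, 2100-2115, 2420, 2490-2510`. Ranges are inclusive at
both ends; codes are zero-padded 4-digit strings compared as integers.

**Approximate tertiles on discrete grids.** Disability and cognition scores
are discrete, so an exact tertile boundary rarely exists. The derived
cutoff is the observed grid value whose classified positive fraction is
closest to the nominal fraction (1/3; or 1/4, 1/5, 1/2 under the
sensitivity modes), ties broken toward the more inclusive cutoff. With a
large zero mass in the disability score this correctly returns a cutoff of
0 with a positive fraction well above 1/3, reproducing the "approximate
tertile" character of the reference cutoffs (disability 0 / ≤ 0.5;
cognition 41+ / 31+; the published preset pins these exactly). A
consequence of the argmin rule is threshold nesting: the positive set under
quintile ⊆ quartile ⊆ tertile ⊆ median, which the sensitivity sweep relies
on and the tests assert.

**Physical function.** Grip strength and FEV₁ are height-standardized
within sex × cohort strata as least-squares residuals on height (a ratio
alternative would change only the within-stratum ordering near the extremes
of height; residuals are the more standard choice and are exactly
mean-zero). The dimension is positive with 3+ of 4 favorable indicators:
standardized grip and FEV₁ strictly above, systolic blood pressure and
pulse strictly below, their cohort (and, for grip/FEV₁, sex) medians.
Values exactly at a median are unfavorable — "above/below median" is read
strictly. The physical medians are *not* varied by the sensitivity modes;
only the disability, cognition and engagement cutoffs move.

**Boundary conventions.** Cognition and disability cutoffs are inclusive in
the printed direction ("41+" means ≥ 41; "≤ 0.5" includes 0.5).

**Missingness.** Any missing component makes its dimension missing, and any
missing dimension makes the count and the all-six indicator missing; such
respondents are excluded from analysis (complete-case on the six
dimensions). Each outcome additionally drops its own missing responses, so
per-outcome denominators differ.

## Outcome coding

Four-level global health ratings: excellent/good favorable, fair/poor not.
Seven-point satisfaction scales: responses 5–7 favorable (7 = most
positive), the neutral midpoint 4 unfavorable. Files using the reverse
orientation should be re-oriented at read time; the package fixes 7 = most
positive internally.

## Estimation

* **Single proportions** — Wilson score 95% intervals. Chosen over Wald for
  its behaviour near 0/100% and small denominators (sparse continuum
  levels); empirical coverage at n = 100, p = 0.3 is checked to be within
  [0.93, 0.97] in the tests.
* **Prevalence differences** — Newcombe's score method (square-and-add
  hybrid of the two Wilson intervals), no continuity correction. Both are
  computed via `statsmodels.stats.proportion`; the test suite verifies them
  against a numerical score-test inversion and the published closed-form
  formula respectively.
* **Mutually adjusted effects** — one additive logistic model per outcome
  with all six dimension indicators; each dimension's effect is reported as
  the marginal-standardization risk difference (average predicted
  probability with the indicator forced to 1 minus forced to 0, over the
  observed covariate distribution). This keeps adjusted effects on the same
  percentage-point scale as the crude differences. With a single predictor
  the model is saturated and the standardized difference equals the crude
  difference exactly (asserted in tests). CIs are percentile bootstrap over
  respondents, default 200 resamples — enough for stable 95% bounds at
  these sample sizes while keeping a full pipeline run in seconds; raise
  `n_boot` for publication-grade intervals. Perfect separation or
  non-convergence flags the estimate rather than raising.
* **Subgroups** — analyses are repeated within cohort, sex, socioeconomic
  class, and a median split of trait negative affect computed on the
  analysis sample (ties at the median go to the "below" group).
  Heterogeneity is checked with a dimension × stratifier interaction term
  in the logistic model (Wald p-value).
* **Multiple testing** — none applied; results are presented as estimates
  with confidence intervals, not hypothesis-test families.
* **Display rounding** — one decimal, half away from zero; all internal
  computation at full precision.

## Synthetic-cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not the survey's sampling design, attrition process or geography.

A single standard-normal latent health factor `z` per respondent drives
everything health-related: linear loadings on grip, FEV₁ (positive) and
blood pressure, pulse (negative); a logit-linear effect on being
disease-free and on having zero disability; a linear loading on the
cognition score; logit-linear effects on all eight engagement items; and a
linear term in the ordered-logit latent response of each self-rated
outcome. Trait negative affect is drawn independently of `z` and enters
*only* the outcome models, with a negative slope. This builds in the
dissociation the design turns on: negative affect shifts self-ratings
(≈ 9–15 points on favorable recent health across the affect median split)
but not the number of positive dimensions, which is how an objective index
can outperform self-report for cross-person comparison.

Marginal prevalences are specified as targets and converted to intercepts
by integrating the logistic link over the latent distribution
(Gauss–Hermite quadrature, 80 nodes), so the defaults hit the emulated
study's conditions in expectation without any fitting: cohort sizes
886/483; disease-free 81.2%/58.0%; disability zero-mass and severity ladder
placing the lowest-tertile cutoffs at 0 and 0.5; cognition means 37.5/27.5
(SD ≈ 8) placing the top-tertile cutoffs at ≈ 41/31; engagement base
probabilities giving ≈ 27% interpersonal-positive and ≈ 20–25%
productive-positive per cohort; favorable outcome targets
68.6/76.2/80.6/88.5%. Outcome latent slopes taper from recent health (1.3)
to life satisfaction (0.9), reproducing the weaker gradients for global
satisfaction. Ordinal outcomes are generated ordered-logit style with
fixed-spacing cutpoints around the solved favorable boundary.

Disease codes: if diseased, one code drawn uniformly from the qualifying
ranges (code identity beyond range membership is irrelevant downstream);
disease-free respondents carry a benign non-qualifying code — including the
excluded skin-cancer code — with probability 0.3, exercising the exclusion
logic.

Missingness is MCAR by default at a per-field rate; an optional
missing-at-random switch scales the rate by `2·expit(−z)` so less healthy
respondents respond less, emulating the reported disadvantage of excluded
respondents. Cohort and sex labels are never masked.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: no real sampling weights or attrition; no
measurement error structure beyond independent noise; dimension-outcome
associations arise from a *single* latent factor, so the generator cannot
distinguish hierarchical from multidirectional interplay between
dimensions; OPCS, AH4 and PANAS score distributions are plausible shapes,
not instrument-calibrated ones; and subgroup effects are homogeneous by
construction, so interaction tests should flag only at the nominal rate.

One known internal inconsistency of the emulated conditions: the dimension
prevalences imply a mean count of ≈ 2.4/2.2 per cohort (the sum of the six
prevalences), and the generator reproduces that; a reported mean near 3.3
is arithmetically incompatible with those prevalences and is not targeted.

## Determinism and numerics

All randomness flows from `numpy.random.default_rng` seeded from the config
(generation) and an explicit seed argument (bootstrap); identical inputs
give byte-identical outputs. Intercept solving uses Brent's method on the
quadrature marginal, tolerance 1e-12. Height regression falls back to
mean-centering when a stratum has zero height variance; a stratum with
fewer than two complete records is an error naming the stratum. Degenerate
analysis inputs (empty cohort, empty analysis sample, one-sided dimensions
within a stratum) raise explicit errors or are skipped with a log entry,
never silently dropped.

## Problem sizes

Default simulations are study-sized (886 + 483). Replicate-based checks in
the test suite use 30–50 replicates at full size, which bounds the
Monte-Carlo standard error of mean prevalence differences at ≈ 0.4
percentage points — tight enough to distinguish the configured effects from
zero and from each other.
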