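# rowekahn

Successful-aging scoring and self-rated health association analysis for
two-cohort surveys of older adults.

## The problem

Gerontology's most widely used objective definition of successful aging —
the Rowe–Kahn model — requires the joint presence of three things: absence
of disease and disability, maintained physical and cognitive function, and
active social engagement (both interpersonal and productive). Whether that
researcher-defined standard captures how older people actually rate their
own health and satisfaction is an empirical question. This package
implements the full operationalization and comparison for a two-cohort
survey design: a pre-retirement cohort ("1952", n ≈ 886, around age 57) and
a post-retirement cohort ("1932", n ≈ 483, around age 76).

Six binary dimensions are scored per respondent, each "positive" relative to
cohort-specific cutoffs:

| dimension | positive when |
|---|---|
| disease-free | no RCGP morbidity code in the chronic-disease ranges (CHD, stroke, COPD, non-skin cancer, diabetes, Parkinson's, serious mental illness) |
| no disability | OPCS disability score in the lowest ≈ tertile (1952: 0; 1932: ≤ 0.5) |
| good physical function | 3+ of 4 of: height-standardized sex-specific grip strength and FEV₁ above the cohort median; systolic BP and pulse below it |
| good cognitive function | AH4 Part-1 score in the top ≈ tertile (1952: 41+; 1932: 31+) |
| good interpersonal engagement | all 3 of: living with partner, recent contact with family/friends, regular club/class attendance |
| good productive engagement | 3+ (1952) / 2+ (1932) of 5: work/training, volunteering, childcare, supporting others, group membership |

The count of positive dimensions (0–6) is the **successful-aging
continuum**; all six positive is the conventional binary definition. Four
self-rated outcomes are dichotomized: recent general health and health for
age (excellent/good vs fair/poor), and 7-point satisfaction with health and
with life (the three most positive responses vs neutral or negative).

The statistical layer estimates favorable-outcome prevalences (Wilson 95%
CIs), prevalence differences for positive vs not-positive dimensions
(Newcombe score CIs), mutually adjusted dimension effects (one logistic
model per outcome with all six indicators, summarised as
marginal-standardization risk differences ΔP = E[P̂(Y=1 | X_j=1, X_{-j})] −
E[P̂(Y=1 | X_j=0, X_{-j})] with bootstrap CIs), subgroup-stratified
analyses with interaction tests, the continuum gradient, and a
threshold-sensitivity sweep (tertile → quartile → quintile → median
cutoffs).

Because the source cohort data are not public, the package ships a seeded
synthetic-cohort generator in which a single latent health factor drives
all dimensions and outcomes, and trait negative affect — drawn
independently of latent health — shifts only the self-rated outcomes. Every
stage of the pipeline is therefore runnable and testable end to end.

## Worked example

```python
from rowekahn import (SimulationConfig, generate_cohorts, standardize_physical,
                      derive_thresholds, build_profiles, code_outcomes,
                      adjusted_dimension_effects)

records  = standardize_physical(generate_cohorts(SimulationConfig(seed=20)))
profiles = build_profiles(records, derive_thresholds(records, "tertile"))
outcomes = code_outcomes(records)
for e in adjusted_dimension_effects(profiles, outcomes, n_boot=200, seed=20):
    if e.outcome == "recent_good":
        print(f"{e.dimension:<20} {e.difference:+5.1f} ({e.ci_low:+5.1f},{e.ci_high:+5.1f})"
              f"  adj {e.adjusted_difference:+5.1f}")
```

prints

```
disease_free         +16.8 (+11.2,+22.3)  adj  +8.6
no_disability        +17.8 (+12.9,+22.5)  adj +10.7
physical_good        +24.7 (+19.9,+29.2)  adj +16.4
cognitive_good       +20.1 (+15.2,+24.7)  adj +12.8
interpersonal_good   +14.9 ( +9.5,+19.8)  adj  +9.0
productive_good      +11.4 ( +5.7,+16.7)  adj  +4.5
```

Each line is the percentage-point difference in good self-rated recent
health between respondents positive versus not positive on that dimension,
with its 95% CI; the adjusted figure is the same contrast holding the other
five dimensions fixed. All six crude differences are positive — every
positive dimension goes with better self-rated health — and adjustment
attenuates but does not remove them, so each dimension contributes
independently. The `examples/` scripts walk through simulation, scoring,
association analysis, and the continuum/sensitivity outputs one capability
at a time.

A thin CLI mirrors the pipeline stages:

```
rowekahn simulate --out data.csv --seed 1
rowekahn score    --in data.csv --out profiles.csv --threshold-mode tertile
rowekahn analyze  --in data.csv --out report/ --seed 1
```

`analyze` writes one tidy CSV per table (dimension prevalences, outcome
prevalences by subgroup, crude+adjusted associations, continuum,
count distribution, sensitivity, heterogeneity) plus a `report.json` bundle
with a provenance block.

## Participant CSV schema

One row per respondent; columns: `cohort` (1952/1932), `sex`, `ses`,
`height` (cm), `grip` (kg), `fev1` (L), `sbp` (mmHg), `pulse` (bpm),
`opcs_score` (≥ 0), `ah4_score` (integer), `rcgp_codes`
(semicolon-delimited 4-digit codes; `-` for none), eight 0/1 engagement
items, `negative_affect` (trait score), `srh_recent`/`srh_for_age`
(excellent/good/fair/poor), `sat_health`/`sat_life` (1–7, 7 most positive).
Missing values are empty cells; `cohort` and `sex` must be present.

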