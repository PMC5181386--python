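"""Configuration for the synthetic two-cohort survey generator.

The generator emulates a pair of community cohorts of older adults ("1952",
pre-retirement age, and "1932", post-retirement age) whose health-related
variables are all driven by a single latent health factor.  Marginal
prevalences (disease-free fraction, favorable self-rated outcome fractions,
zero-disability mass) are specified as targets and converted to logit
intercepts by integrating the logistic link over the latent distribution, so
a default-configured simulation reproduces the study conditions in
expectation without any fitting.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit

COHORT_YOUNG = "1952"
COHORT_OLD = "1932"
COHORTS = (COHORT_YOUNG, COHORT_OLD)

SEXES = ("female", "male")
SES_LEVELS = ("nonmanual", "manual")

FOUR_LEVELS = ("poor", "fair", "good", "excellent")

INTERPERSONAL_ITEMS = ("lives_with_partner", "contact_4wk", "club_attendance")
PRODUCTIVE_ITEMS = (
    "work_training",
    "voluntary_work",
    "childcare",
    "support_other",
    "group_member",
)
ENGAGEMENT_ITEMS = INTERPERSONAL_ITEMS + PRODUCTIVE_ITEMS

OUTCOME_FIELDS = ("srh_recent", "srh_for_age", "sat_health", "sat_life")

# 80-node Gauss-Hermite rule; accurate to ~1e-12 for logistic-normal integrals
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(80)


def expected_expit(intercept: float, scale_sd: float) -> float:
    """E[expit(intercept + X)] for X ~ Normal(0, scale_sd)."""
    x = np.sqrt(2.0) * scale_sd * _GH_X + intercept
    return float(np.sum(_GH_W * expit(x)) / np.sqrt(np.pi))


def solve_logit_intercept(target: float, scale_sd: float) -> float:
    """Intercept a such that E[expit(a + X)] = target for X ~ Normal(0, scale_sd).

    Used to turn a target marginal prevalence into the intercept of a
    logit-linear model with a normally distributed linear predictor.
    """
    if not 0.0 < target < 1.0:
        raise ValueError(f"target prevalence must be in (0, 1), got {target}")
    return float(
        brentq(lambda a: expected_expit(a, scale_sd) - target, -40.0, 40.0, xtol=1e-12)
    )


class EngagementItem(BaseModel):
    """One binary social-engagement item: base probability per cohort at the
    latent mean, plus a logit-scale slope on latent health."""

    p_young: float = Field(ge=0.0, le=1.0)
    p_old: float = Field(ge=0.0, le=1.0)
    slope: float = 0.0

    def base_prob(self, cohort: str) -> float:
        return self.p_young if cohort == COHORT_YOUNG else self.p_old


class OutcomeSpec(BaseModel):
    """Ordered-logit generator for one self-rated outcome.

    The latent response is ``intercept + latent_slope*z + affect_slope*na``
    plus standard-logistic noise, thresholded at fixed cutpoints.  The
    intercept is positioned so that the marginal probability of a *favorable*
    response equals ``favorable_target``; it may also be set explicitly.
    """

    latent_slope: float
    affect_slope: float
    favorable_target: float = Field(gt=0.0, lt=1.0)
    intercept: Optional[float] = None
    # spacing of the remaining ordinal cutpoints around the favorable one
    cut_spacing: float = Field(default=1.4, gt=0.0)

    def resolved_intercept(self, latent_sd: float) -> float:
        if self.intercept is not None:
            return self.intercept
        sd = float(np.hypot(self.latent_slope * latent_sd, self.affect_slope))
        return solve_logit_intercept(self.favorable_target, sd)

    def cutpoints(self, latent_sd: float, n_levels: int) -> np.ndarray:
        """Cutpoints c_1 < ... < c_{n-1} on the latent-response scale.

        The favorable boundary (between level 2|3 of four, or 4|5 of seven) is
        -intercept; the others are spaced ``cut_spacing`` apart.
        """
        c_fav = -self.resolved_intercept(latent_sd)
        if n_levels == 4:
            fav_index = 1  # cut between fair and good
        elif n_levels == 7:
            fav_index = 3  # cut between neutral (4) and happy (5)
        else:
            raise ValueError(f"unsupported ordinal scale with {n_levels} levels")
        offsets = (np.arange(n_levels - 1) - fav_index) * self.cut_spacing
        return c_fav + offsets


class PhysioSpec(BaseModel):
    """Linear model for one continuous physiological measure."""

    mean_female: float
    mean_male: float
    cohort_shift_old: float = 0.0  # added to the mean in the 1932 cohort
    height_slope: float = 0.0  # per cm deviation from the sex mean height
    loading: float = 0.0  # effect of latent health (filled from physio_loadings)
    noise_sd: float = Field(gt=0.0)


def _default_physio_params() -> dict[str, PhysioSpec]:
    return {
        "grip": PhysioSpec(
            mean_female=26.0, mean_male=44.0, cohort_shift_old=-6.0,
            height_slope=0.30, noise_sd=6.0,
        ),
        "fev1": PhysioSpec(
            mean_female=2.5, mean_male=3.4, cohort_shift_old=-0.9,
            height_slope=0.030, noise_sd=0.45,
        ),
        "sbp": PhysioSpec(
            mean_female=132.0, mean_male=134.0, cohort_shift_old=10.0,
            noise_sd=15.0,
        ),
        "pulse": PhysioSpec(
            mean_female=73.0, mean_male=71.0, cohort_shift_old=0.0,
            noise_sd=10.0,
        ),
    }


def _default_engagement() -> dict[str, EngagementItem]:
    # Base probabilities chosen so that "most engaged tertile" rules
    # (all 3 interpersonal items; 3+/2+ of 5 productive items) hold for
    # roughly a quarter of each cohort, with working-age items concentrated
    # in the younger cohort.
    return {
        "lives_with_partner": EngagementItem(p_young=0.74, p_old=0.62, slope=0.5),
        "contact_4wk": EngagementItem(p_young=0.90, p_old=0.87, slope=0.3),
        "club_attendance": EngagementItem(p_young=0.40, p_old=0.46, slope=0.6),
        "work_training": EngagementItem(p_young=0.62, p_old=0.04, slope=0.3),
        "voluntary_work": EngagementItem(p_young=0.18, p_old=0.16, slope=0.4),
        "childcare": EngagementItem(p_young=0.24, p_old=0.15, slope=0.2),
        "support_other": EngagementItem(p_young=0.40, p_old=0.27, slope=0.3),
        "group_member": EngagementItem(p_young=0.30, p_old=0.30, slope=0.5),
    }


def _default_outcomes() -> dict[str, OutcomeSpec]:
    # Favorable targets are the overall observed fractions in the emulated
    # study (good recent health 68.6%, good health for age 76.2%, satisfied
    # with health 80.6%, satisfied with life 88.5%).  Latent slopes taper
    # from recent health to life satisfaction, mirroring the weaker gradients
    # for global satisfaction; the negative-affect slope is equal across
    # outcomes and enters nowhere else in the generator.
    return {
        "srh_recent": OutcomeSpec(latent_slope=1.3, affect_slope=-0.55, favorable_target=0.686),
        "srh_for_age": OutcomeSpec(latent_slope=1.2, affect_slope=-0.55, favorable_target=0.762),
        "sat_health": OutcomeSpec(latent_slope=1.0, affect_slope=-0.55, favorable_target=0.806),
        "sat_life": OutcomeSpec(latent_slope=0.9, affect_slope=-0.55, favorable_target=0.885),
    }


class SimulationConfig(BaseModel):
    """All parameters of the synthetic cohort generator.

    Negative affect is structurally dissociated from the successful-aging
    dimensions: it appears only in the ``affect_slope`` of ``outcome_logits``
    and is drawn independently of the latent health factor, so it shifts
    self-rated outcomes but not dimension counts.
    """

    n_young: int = Field(default=886, ge=1)
    n_old: int = Field(default=483, ge=1)
    latent_sd: float = Field(default=1.0, gt=0.0)

    female_prob: float = Field(default=0.55, ge=0.0, le=1.0)

    # P(manual SES) marginal target; manual class is more likely at low
    # latent health, driving the SES gradient in dimensions and outcomes.
    manual_target: float = Field(default=0.29, gt=0.0, lt=1.0)
    manual_latent_slope: float = -0.8

    # disease-free marginal targets (1952: 81.2%, 1932: 58.0%); intercepts
    # solved from them unless given explicitly
    disease_free_targets: dict[str, float] = Field(
        default_factory=lambda: {COHORT_YOUNG: 0.812, COHORT_OLD: 0.580}
    )
    disease_logit_intercepts: Optional[dict[str, float]] = None
    disease_logit_slope: float = 1.0
    # chance that a disease-free respondent carries a benign (non-qualifying)
    # morbidity code
    benign_code_prob: float = Field(default=0.3, ge=0.0, le=1.0)

    # disability score: zero-inflated, step-0.5 severity ladder
    opcs_zero_targets: dict[str, float] = Field(
        default_factory=lambda: {COHORT_YOUNG: 0.448, COHORT_OLD: 0.25}
    )
    opcs_zero_slope: float = 1.2
    opcs_severity_geom_p: dict[str, float] = Field(
        default_factory=lambda: {COHORT_YOUNG: 0.35, COHORT_OLD: 0.20}
    )

    # cognition: integer score, cohort-shifted, loading on latent health;
    # total SD ~8 puts the top-tertile boundary near the published cutoffs
    ah4_mean: dict[str, float] = Field(
        default_factory=lambda: {COHORT_YOUNG: 37.5, COHORT_OLD: 27.5}
    )
    ah4_latent_loading: float = 4.0
    ah4_resid_sd: float = Field(default=6.93, gt=0.0)

    height_mean: dict[str, float] = Field(
        default_factory=lambda: {"female": 160.0, "male": 174.0}
    )
    height_sd: dict[str, float] = Field(
        default_factory=lambda: {"female": 6.0, "male": 7.0}
    )

    physio_loadings: dict[str, float] = Field(
        default_factory=lambda: {"grip": 4.0, "fev1": 0.35, "sbp": -6.0, "pulse": -4.0}
    )
    physio_params: dict[str, PhysioSpec] = Field(default_factory=_default_physio_params)

    engagement_probs: dict[str, EngagementItem] = Field(default_factory=_default_engagement)

    outcome_logits: dict[str, OutcomeSpec] = Field(default_factory=_default_outcomes)

    missing_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    missing_mar: bool = False  # if True, missingness rises as latent health falls
    mar_strength: float = Field(default=1.0, ge=0.0)

    seed: int = 0

    @field_validator("disease_free_targets", "opcs_zero_targets")
    @classmethod
    def _targets_in_unit_interval(cls, v: dict[str, float], info) -> dict[str, float]:
        for cohort, p in v.items():
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"{info.field_name}[{cohort}] must be in (0, 1), got {p}"
                )
        return v

    @field_validator("opcs_severity_geom_p")
    @classmethod
    def _geom_p_valid(cls, v: dict[str, float], info) -> dict[str, float]:
        for cohort, p in v.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(
                    f"{info.field_name}[{cohort}] must be in (0, 1], got {p}"
                )
        return v

    @model_validator(mode="after")
    def _check_cohort_keys(self) -> "SimulationConfig":
        for name in ("disease_free_targets", "opcs_zero_targets",
                     "opcs_severity_geom_p", "ah4_mean"):
            keys = set(getattr(self, name))
            if keys != set(COHORTS):
                raise ValueError(f"{name} must have exactly the cohort keys {COHORTS}")
        if set(self.engagement_probs) != set(ENGAGEMENT_ITEMS):
            raise ValueError(
                f"engagement_probs must have exactly the item keys {ENGAGEMENT_ITEMS}"
            )
        if set(self.outcome_logits) != set(OUTCOME_FIELDS):
            raise ValueError(
                f"outcome_logits must have exactly the outcome keys {OUTCOME_FIELDS}"
            )
        return self

    def resolved_disease_intercepts(self) -> dict[str, float]:
        if self.disease_logit_intercepts is not None:
            return self.disease_logit_intercepts
        sd = abs(self.disease_logit_slope) * self.latent_sd
        return {
            c: solve_logit_intercept(t, sd) for c, t in self.disease_free_targets.items()
        }

    def resolved_opcs_zero_intercepts(self) -> dict[str, float]:
        sd = abs(self.opcs_zero_slope) * self.latent_sd
        return {
            c: solve_logit_intercept(t, sd) for c, t in self.opcs_zero_targets.items()
        }

    def expected_disease_free(self, cohort: str) -> float:
        """Marginal disease-free probability implied by the config, by quadrature."""
        a = self.resolved_disease_intercepts()[cohort]
        return expected_expit(a, abs(self.disease_logit_slope) * self.latent_sd)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a YAML or JSON file (YAML is a JSON superset)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))
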