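"""Synthetic two-cohort survey generator.

Emulates the statistical structure of a two-cohort community survey of older
adults: a per-person standard-normal latent health factor drives chronic
disease, disability, physiological and cognitive function, social-engagement
items and the four self-rated outcomes; trait negative affect is drawn
independently of latent health and shifts only the self-rated outcomes.  The
1932 cohort carries a configurably heavier disease and disability burden than
the 1952 cohort.

All randomness flows from ``numpy.random.default_rng`` seeded from the
config, so a fixed config yields byte-identical output.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .codes import CodeRangeSet, default_disease_codes
from .config import (
    COHORT_OLD,
    COHORT_YOUNG,
    ENGAGEMENT_ITEMS,
    FOUR_LEVELS,
    OUTCOME_FIELDS,
    SimulationConfig,
    solve_logit_intercept,
)

#: Column order of the participant table; one row per respondent.
PARTICIPANT_COLUMNS = [
    "cohort", "sex", "ses",
    "height", "grip", "fev1", "sbp", "pulse",
    "opcs_score", "ah4_score", "rcgp_codes",
    "lives_with_partner", "contact_4wk", "club_attendance",
    "work_training", "voluntary_work", "childcare", "support_other",
    "group_member",
    "negative_affect",
    "srh_recent", "srh_for_age", "sat_health", "sat_life",
]

#: Fields that missingness injection may blank; cohort and sex labels never are.
MASKABLE_FIELDS = [c for c in PARTICIPANT_COLUMNS if c not in ("cohort", "sex")]

_BOOL_FIELDS = list(ENGAGEMENT_ITEMS)

# benign (non-qualifying) morbidity codes occasionally carried by
# disease-free respondents; 0455 is the excluded skin-cancer code
_BENIGN_CODES = ["0455", "0100", "1500", "2600", "3005"]


def _ordinal_draw(rng: np.random.Generator, eta: np.ndarray,
                  cutpoints: np.ndarray) -> np.ndarray:
    """Ordered-logit draw: level = 1 + #{cutpoints below latent response}."""
    y_star = eta + rng.logistic(size=eta.shape[0])
    return 1 + (y_star[:, None] > cutpoints[None, :]).sum(axis=1)


def _generate_cohort(cohort: str, n: int, config: SimulationConfig,
                     rng: np.random.Generator,
                     code_set: CodeRangeSet) -> pd.DataFrame:
    z = rng.normal(0.0, config.latent_sd, size=n)
    na = rng.normal(0.0, 1.0, size=n)  # trait negative affect, independent of z

    sex = np.where(rng.random(n) < config.female_prob, "female", "male")
    is_male = sex == "male"

    manual_a = solve_logit_intercept(
        config.manual_target, abs(config.manual_latent_slope) * config.latent_sd
    )
    ses = np.where(
        rng.random(n) < expit(manual_a + config.manual_latent_slope * z),
        "manual", "nonmanual",
    )

    height = np.where(
        is_male,
        rng.normal(config.height_mean["male"], config.height_sd["male"], size=n),
        rng.normal(config.height_mean["female"], config.height_sd["female"], size=n),
    )
    sex_mean_height = np.where(
        is_male, config.height_mean["male"], config.height_mean["female"]
    )

    physio: dict[str, np.ndarray] = {}
    for name, spec in config.physio_params.items():
        mean = np.where(is_male, spec.mean_male, spec.mean_female)
        if cohort == COHORT_OLD:
            mean = mean + spec.cohort_shift_old
        loading = config.physio_loadings.get(name, spec.loading)
        values = (
            mean
            + spec.height_slope * (height - sex_mean_height)
            + loading * z
            + rng.normal(0.0, spec.noise_sd, size=n)
        )
        physio[name] = np.maximum(values, 0.1)  # physical measures are positive

    # disability: zero-inflated 0.5-step severity ladder; more disability at
    # lower latent health
    p_zero = expit(
        config.resolved_opcs_zero_intercepts()[cohort] + config.opcs_zero_slope * z
    )
    is_zero = rng.random(n) < p_zero
    severity = 0.5 * rng.geometric(config.opcs_severity_geom_p[cohort], size=n)
    opcs = np.where(is_zero, 0.0, severity)

    ah4 = np.rint(
        config.ah4_mean[cohort]
        + config.ah4_latent_loading * z
        + rng.normal(0.0, config.ah4_resid_sd, size=n)
    )
    ah4 = np.maximum(ah4, 0).astype(int)

    # chronic disease: draw disease-free status, then a qualifying code if
    # diseased; disease-free respondents may carry a benign code
    a = config.resolved_disease_intercepts()[cohort]
    disease_free = rng.random(n) < expit(a + config.disease_logit_slope * z)
    qualifying = code_set.members()
    codes: list[list[str]] = []
    for i in range(n):
        if disease_free[i]:
            if rng.random() < config.benign_code_prob:
                codes.append([_BENIGN_CODES[rng.integers(len(_BENIGN_CODES))]])
            else:
                codes.append([])
        else:
            codes.append([qualifying[rng.integers(len(qualifying))]])

    engagement: dict[str, np.ndarray] = {}
    for item in ENGAGEMENT_ITEMS:
        spec = config.engagement_probs[item]
        p = expit(logit(np.clip(spec.base_prob(cohort), 1e-9, 1 - 1e-9)) + spec.slope * z)
        engagement[item] = rng.random(n) < p

    outcomes: dict[str, np.ndarray] = {}
    for field in OUTCOME_FIELDS:
        spec = config.outcome_logits[field]
        eta = spec.latent_slope * z + spec.affect_slope * na
        n_levels = 4 if field.startswith("srh") else 7
        level = _ordinal_draw(rng, eta, spec.cutpoints(config.latent_sd, n_levels))
        if n_levels == 4:
            outcomes[field] = np.array(FOUR_LEVELS)[level - 1]
        else:
            outcomes[field] = level

    df = pd.DataFrame({
        "cohort": cohort,
        "sex": sex,
        "ses": ses,
        "height": np.round(height, 1),
        "grip": np.round(physio["grip"], 1),
        "fev1": np.round(physio["fev1"], 2),
        "sbp": np.round(physio["sbp"], 0),
        "pulse": np.round(physio["pulse"], 0),
        "opcs_score": opcs,
        "ah4_score": ah4,
        "rcgp_codes": codes,
        **{item: engagement[item] for item in ENGAGEMENT_ITEMS},
        "negative_affect": np.round(na, 3),
        **outcomes,
    })
    df["_latent"] = z
    return df


def generate_cohorts(config: Optional[SimulationConfig] = None,
                     code_set: Optional[CodeRangeSet] = None,
                     keep_latent: bool = False) -> pd.DataFrame:
    """Generate the two-cohort participant table.

    Returns ``config.n_young + config.n_old`` rows with the documented
    participant schema (younger cohort first).  If ``config.missing_rate`` is
    positive, per-field missingness is injected (MCAR, or MAR on latent
    health when ``config.missing_mar`` is set).  ``keep_latent`` retains the
    ``_latent`` health factor column for diagnostics.
    """
    if config is None:
        config = SimulationConfig()
    if code_set is None:
        code_set = default_disease_codes()
    rng = np.random.default_rng(config.seed)
    young = _generate_cohort(COHORT_YOUNG, config.n_young, config, rng, code_set)
    old = _generate_cohort(COHORT_OLD, config.n_old, config, rng, code_set)
    df = pd.concat([young, old], ignore_index=True)
    df = _coerce_dtypes(df)
    if config.missing_rate > 0:
        df = inject_missingness(
            df,
            config.missing_rate,
            seed=rng.integers(2**31),
            latent=df["_latent"].to_numpy() if config.missing_mar else None,
            mar_strength=config.mar_strength,
        )
    if not keep_latent:
        df = df.drop(columns="_latent")
    return df


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _BOOL_FIELDS:
        df[col] = df[col].astype("boolean")
    for col in ("sat_health", "sat_life", "ah4_score"):
        df[col] = df[col].astype("Int64")
    return df


def inject_missingness(records: pd.DataFrame, rate: float,
                       seed: int | np.random.Generator = 0,
                       latent: Optional[np.ndarray] = None,
                       mar_strength: float = 1.0) -> pd.DataFrame:
    """Blank each maskable field independently with probability ``rate``.

    Cohort and sex labels are never masked.  When ``latent`` is supplied the
    per-row rate is modulated as ``rate * 2*expit(-mar_strength*z)`` (missing
    at random given latent health, mean rate preserved at the latent mean),
    emulating heavier nonresponse among less healthy respondents.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"missingness rate must be in [0, 1], got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = records.copy()
    n = len(out)
    if latent is not None:
        row_rate = np.minimum(rate * 2.0 * expit(-mar_strength * np.asarray(latent)), 1.0)
    else:
        row_rate = np.full(n, rate)
    for col in MASKABLE_FIELDS:
        if col not in out.columns:
            continue
        mask = rng.random(n) < row_rate
        if out[col].dtype == object:  # rcgp_codes holds lists
            out[col] = out[col].where(~mask, other=np.nan)
        else:
            out.loc[mask, col] = pd.NA if str(out[col].dtype) in ("boolean", "Int64") else np.nan
    return out
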