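"""Rowe-Kahn successful-aging dimension scoring.

Six binary dimensions are scored per respondent, each "positive" relative to
cohort-specific thresholds:

* **disease-free** — no morbidity code in the qualifying chronic-disease set;
* **no disability** — disability severity score in the lowest (approximate)
  cohort tertile;
* **good physical functioning** — 3+ of 4 of: height-standardized
  sex-specific grip strength and FEV1 strictly above the cohort median,
  systolic blood pressure and pulse strictly below the cohort median;
* **good cognitive functioning** — cognition score in the top cohort tertile;
* **good interpersonal engagement** — all 3 interpersonal items positive;
* **good productive engagement** — 3+ (younger cohort) or 2+ (older cohort)
  of 5 productive items positive.

The continuum score is the count of positive dimensions (0-6); conventional
binary successful aging is all six positive.  Any missing component makes
its dimension — and hence the count — missing.

Boundary conventions: the disability and cognition cutoffs are inclusive in
the printed direction ("<= 0.5", "41+"); physical-median comparisons are
strict, so a value exactly at the median is unfavorable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codes import CodeRangeSet, default_disease_codes
from .config import (
    COHORT_OLD,
    COHORT_YOUNG,
    COHORTS,
    INTERPERSONAL_ITEMS,
    PRODUCTIVE_ITEMS,
    SEXES,
)

DIMENSIONS = (
    "disease_free",
    "no_disability",
    "physical_good",
    "cognitive_good",
    "interpersonal_good",
    "productive_good",
)

THRESHOLD_MODES = ("tertile", "quartile", "quintile", "median")
#: nominal positive fraction targeted by each threshold mode
MODE_FRACTIONS = {"tertile": 1 / 3, "quartile": 1 / 4, "quintile": 1 / 5, "median": 1 / 2}


class ThresholdError(ValueError):
    """Raised when thresholds cannot be derived from the data supplied."""


@dataclass(frozen=True)
class CohortThresholds:
    """Cutoffs defining 'positive' dimensions within one cohort."""

    opcs_cutoff: float  # no-disability maximum (inclusive)
    ah4_cutoff: int  # cognition minimum (inclusive)
    productive_min: int  # minimum positive productive items
    interpersonal_min: int  # minimum positive interpersonal items
    sbp_median: float
    pulse_median: float
    grip_median: Mapping[str, float]  # by sex, on the height-residual scale
    fev1_median: Mapping[str, float]


@dataclass(frozen=True)
class ThresholdSet:
    mode: str
    cohorts: Mapping[str, CohortThresholds]

    def __getitem__(self, cohort: str) -> CohortThresholds:
        return self.cohorts[cohort]


def _is_missing(value) -> bool:
    if value is None or value is pd.NA:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


# ---------------------------------------------------------------------------
# scalar per-record classifiers
# ---------------------------------------------------------------------------

def classify_disease_free(rcgp_codes, code_set: CodeRangeSet):
    """True iff no code falls in the qualifying chronic-disease set."""
    if _is_missing(rcgp_codes):
        return pd.NA
    return not any(code in code_set for code in rcgp_codes)


def classify_no_disability(opcs_score, cohort: str, thresholds: ThresholdSet):
    if _is_missing(opcs_score):
        return pd.NA
    if opcs_score < 0:
        raise ValueError(f"disability score must be nonnegative, got {opcs_score}")
    return bool(opcs_score <= thresholds[cohort].opcs_cutoff)


def classify_cognitive(ah4_score, cohort: str, thresholds: ThresholdSet):
    if _is_missing(ah4_score):
        return pd.NA
    return bool(ah4_score >= thresholds[cohort].ah4_cutoff)


def classify_physical(std_grip, std_fev1, sbp, pulse, cohort: str, sex: str,
                      thresholds: ThresholdSet):
    """3+ of 4 favorable; comparisons with the medians are strict."""
    values = (std_grip, std_fev1, sbp, pulse)
    if any(_is_missing(v) for v in values):
        return pd.NA
    t = thresholds[cohort]
    favorable = (
        int(std_grip > t.grip_median[sex])
        + int(std_fev1 > t.fev1_median[sex])
        + int(sbp < t.sbp_median)
        + int(pulse < t.pulse_median)
    )
    return favorable >= 3


def classify_interpersonal(items: Sequence, thresholds: ThresholdSet,
                           cohort: str = COHORT_YOUNG):
    if any(_is_missing(v) for v in items):
        return pd.NA
    return sum(bool(v) for v in items) >= thresholds[cohort].interpersonal_min


def classify_productive(items: Sequence, cohort: str, thresholds: ThresholdSet):
    if any(_is_missing(v) for v in items):
        return pd.NA
    return sum(bool(v) for v in items) >= thresholds[cohort].productive_min


def build_profile(record: Mapping, thresholds: ThresholdSet,
                  code_set: Optional[CodeRangeSet] = None) -> dict:
    """Score one respondent; expects ``std_grip``/``std_fev1`` in the record.

    Returns the six indicators plus ``count`` (0-6, missing when any
    indicator is missing) and ``all_six``.
    """
    if code_set is None:
        code_set = default_disease_codes()
    cohort = record["cohort"]
    profile = {
        "disease_free": classify_disease_free(record["rcgp_codes"], code_set),
        "no_disability": classify_no_disability(record["opcs_score"], cohort, thresholds),
        "physical_good": classify_physical(
            record["std_grip"], record["std_fev1"], record["sbp"], record["pulse"],
            cohort, record["sex"], thresholds,
        ),
        "cognitive_good": classify_cognitive(record["ah4_score"], cohort, thresholds),
        "interpersonal_good": classify_interpersonal(
            [record[k] for k in INTERPERSONAL_ITEMS], thresholds, cohort
        ),
        "productive_good": classify_productive(
            [record[k] for k in PRODUCTIVE_ITEMS], cohort, thresholds
        ),
    }
    if any(v is pd.NA for v in profile.values()):
        profile["count"] = pd.NA
        profile["all_six"] = pd.NA
    else:
        profile["count"] = sum(int(v) for v in profile.values())
        profile["all_six"] = profile["count"] == 6
    return profile


# ---------------------------------------------------------------------------
# height standardization
# ---------------------------------------------------------------------------

def standardize_physical(records: pd.DataFrame) -> pd.DataFrame:
    """Attach height-standardized grip and FEV1 (``std_grip``, ``std_fev1``).

    Standardized values are least-squares residuals of the measure on height
    within each sex-by-cohort stratum, so they are centred at zero within
    stratum and free of the height gradient.  Records missing height or the
    measure get a missing standardized value.  A stratum with fewer than two
    complete records cannot be fit and raises :class:`ThresholdError`.
    """
    out = records.copy()
    for measure in ("grip", "fev1"):
        out[f"std_{measure}"] = np.nan
        for (cohort, sex), idx in records.groupby(["cohort", "sex"]).groups.items():
            sub = records.loc[idx, ["height", measure]].astype(float)
            complete = sub.dropna()
            if len(complete) < 2:
                raise ThresholdError(
                    f"stratum cohort={cohort} sex={sex} has {len(complete)} complete "
                    f"records for {measure}; need at least 2 to standardize"
                )
            h = complete["height"].to_numpy()
            y = complete[measure].to_numpy()
            if np.ptp(h) == 0:  # constant height: residual = deviation from mean
                slope, intercept = 0.0, y.mean()
            else:
                slope, intercept = np.polyfit(h, y, 1)
            resid = sub[measure] - (intercept + slope * sub["height"])
            out.loc[idx, f"std_{measure}"] = resid
    return out


# ---------------------------------------------------------------------------
# threshold derivation
# ---------------------------------------------------------------------------

def _grid_cutoff(values: np.ndarray, nominal: float, direction: str) -> tuple[float, float]:
    """Cutoff on the observed value grid whose positive fraction is closest
    to ``nominal``; ties break toward the more inclusive (larger) fraction.

    ``direction`` is "low" when small values are favorable (positive means
    value <= cutoff) or "high" when large values are (value >= cutoff).
    Returns (cutoff, achieved fraction).
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ThresholdError("no observed values to derive a cutoff from")
    grid = np.unique(values)
    if direction == "low":
        fracs = np.array([(values <= c).mean() for c in grid])
    elif direction == "high":
        fracs = np.array([(values >= c).mean() for c in grid])
    else:
        raise ValueError(f"direction must be 'low' or 'high', got {direction!r}")
    err = np.abs(fracs - nominal)
    best = err.min()
    candidates = np.flatnonzero(np.isclose(err, best))
    chosen = candidates[np.argmax(fracs[candidates])]
    return float(grid[chosen]), float(fracs[chosen])


def _count_cutoff(counts: np.ndarray, nominal: float, max_count: int) -> int:
    """Minimum-count cutoff over 0..max_count by the same closest-fraction rule."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[~np.isnan(counts)]
    if counts.size == 0:
        raise ThresholdError("no observed counts to derive a cutoff from")
    grid = np.arange(0, max_count + 1)
    fracs = np.array([(counts >= m).mean() for m in grid])
    err = np.abs(fracs - nominal)
    best = err.min()
    candidates = np.flatnonzero(np.isclose(err, best))
    chosen = candidates[np.argmax(fracs[candidates])]
    return int(grid[chosen])


#: Published cohort-specific cutoffs for the default (tertile) analysis.
PUBLISHED_CUTOFFS = {
    COHORT_YOUNG: {"opcs_cutoff": 0.0, "ah4_cutoff": 41, "productive_min": 3,
                   "interpersonal_min": 3},
    COHORT_OLD: {"opcs_cutoff": 0.5, "ah4_cutoff": 31, "productive_min": 2,
                 "interpersonal_min": 3},
}


def derive_thresholds(records: pd.DataFrame, mode: str = "tertile") -> ThresholdSet:
    """Derive cohort-relative thresholds from the data.

    ``mode`` is one of "tertile", "quartile", "quintile", "median" (nominal
    positive fractions 1/3, 1/4, 1/5, 1/2) or "published", which fixes the
    disability/cognition/engagement cutoffs at their published values.
    Because the scores are discrete, empirical cutoffs are the grid values
    whose positive fraction is closest to nominal ("approximate tertiles").
    Physical-function medians are always the within-stratum medians of the
    height-standardized measures, whatever the mode.
    """
    if mode != "published" and mode not in THRESHOLD_MODES:
        raise ThresholdError(
            f"unknown threshold mode {mode!r}; expected one of "
            f"{THRESHOLD_MODES + ('published',)}"
        )
    if not {"std_grip", "std_fev1"}.issubset(records.columns):
        records = standardize_physical(records)

    cohorts = {}
    for cohort in COHORTS:
        sub = records[records["cohort"] == cohort]
        if sub.empty:
            raise ThresholdError(f"no records for cohort {cohort}")
        medians = {
            "sbp_median": float(sub["sbp"].median()),
            "pulse_median": float(sub["pulse"].median()),
            "grip_median": {
                s: float(sub.loc[sub["sex"] == s, "std_grip"].median()) for s in SEXES
            },
            "fev1_median": {
                s: float(sub.loc[sub["sex"] == s, "std_fev1"].median()) for s in SEXES
            },
        }
        if mode == "published":
            cohorts[cohort] = CohortThresholds(**PUBLISHED_CUTOFFS[cohort], **medians)
            continue
        nominal = MODE_FRACTIONS[mode]
        opcs_cutoff, _ = _grid_cutoff(
            sub["opcs_score"].astype("Float64").to_numpy(dtype=float, na_value=np.nan),
            nominal, "low",
        )
        ah4_cutoff, _ = _grid_cutoff(
            sub["ah4_score"].astype("Float64").to_numpy(dtype=float, na_value=np.nan),
            nominal, "high",
        )
        inter_counts = sub[list(INTERPERSONAL_ITEMS)].astype("float").sum(
            axis=1, skipna=False
        )
        prod_counts = sub[list(PRODUCTIVE_ITEMS)].astype("float").sum(
            axis=1, skipna=False
        )
        cohorts[cohort] = CohortThresholds(
            opcs_cutoff=opcs_cutoff,
            ah4_cutoff=int(ah4_cutoff),
            interpersonal_min=_count_cutoff(inter_counts.to_numpy(float), nominal, 3),
            productive_min=_count_cutoff(prod_counts.to_numpy(float), nominal, 5),
            **medians,
        )
    return ThresholdSet(mode=mode, cohorts=cohorts)


# ---------------------------------------------------------------------------
# vectorized profile construction
# ---------------------------------------------------------------------------

def build_profiles(records: pd.DataFrame, thresholds: ThresholdSet,
                   code_set: Optional[CodeRangeSet] = None) -> pd.DataFrame:
    """Score every respondent; returns the six dimension indicators (nullable
    boolean), ``count`` (nullable Int64) and ``all_six``, indexed like
    ``records``."""
    if code_set is None:
        code_set = default_disease_codes()
    if not {"std_grip", "std_fev1"}.issubset(records.columns):
        records = standardize_physical(records)

    n = len(records)
    out = pd.DataFrame(index=records.index)

    out["disease_free"] = pd.array(
        [classify_disease_free(c, code_set) for c in records["rcgp_codes"]],
        dtype="boolean",
    )

    opcs = records["opcs_score"].astype(float)
    if (opcs.dropna() < 0).any():
        bad = records.index[opcs < 0][0]
        raise ValueError(f"negative disability score at row {bad}")
    ah4 = records["ah4_score"].astype("Float64")

    disab = pd.array([pd.NA] * n, dtype="boolean")
    cog = pd.array([pd.NA] * n, dtype="boolean")
    phys = pd.array([pd.NA] * n, dtype="boolean")
    for cohort in COHORTS:
        t = thresholds[cohort]
        in_c = (records["cohort"] == cohort).to_numpy()
        disab[in_c] = pd.array(opcs <= t.opcs_cutoff, dtype="boolean")[in_c]
        cog[in_c] = pd.array(ah4 >= t.ah4_cutoff, dtype="boolean")[in_c]
        grip_med = records["sex"].map(t.grip_median).astype(float)
        fev1_med = records["sex"].map(t.fev1_median).astype(float)
        favorable = (
            (records["std_grip"] > grip_med).astype(int)
            + (records["std_fev1"] > fev1_med).astype(int)
            + (records["sbp"] < t.sbp_median).astype(int)
            + (records["pulse"] < t.pulse_median).astype(int)
        )
        complete = records[["std_grip", "std_fev1", "sbp", "pulse"]].notna().all(axis=1)
        phys_c = pd.array(favorable >= 3, dtype="boolean")
        phys_c[~complete.to_numpy()] = pd.NA
        phys[in_c] = phys_c[in_c]
    # NaN comparisons are False above; restore missingness
    disab[opcs.isna().to_numpy()] = pd.NA
    cog[ah4.isna().to_numpy()] = pd.NA
    out["no_disability"] = disab
    out["cognitive_good"] = cog
    out["physical_good"] = phys

    inter = records[list(INTERPERSONAL_ITEMS)].astype("boolean")
    inter_count = inter.astype("Int64").sum(axis=1, skipna=False)
    prod = records[list(PRODUCTIVE_ITEMS)].astype("boolean")
    prod_count = prod.astype("Int64").sum(axis=1, skipna=False)
    inter_min = records["cohort"].map(
        {c: thresholds[c].interpersonal_min for c in COHORTS}
    )
    prod_min = records["cohort"].map(
        {c: thresholds[c].productive_min for c in COHORTS}
    )
    out["interpersonal_good"] = (inter_count >= inter_min).astype("boolean")
    out["productive_good"] = (prod_count >= prod_min).astype("boolean")

    out = out[list(DIMENSIONS)]
    out["count"] = out[list(DIMENSIONS)].astype("Int64").sum(axis=1, skipna=False)
    out["all_six"] = (out["count"] == 6).astype("boolean")
    out.loc[out["count"].isna(), "all_six"] = pd.NA
    return out
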