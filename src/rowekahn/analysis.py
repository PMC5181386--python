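"""Prevalence and association estimation.

Single proportions get Wilson score 95% intervals; differences between two
independent proportions get Newcombe score intervals (the square-and-add
hybrid of the two Wilson intervals).  Mutually adjusted dimension effects
come from one additive logistic model per outcome with all six dimension
indicators, summarised by marginal standardization: the mean predicted
probability with a dimension set positive for everyone minus set negative
for everyone, a risk difference on the percentage-point scale, with a
nonparametric bootstrap interval over respondents.

Analyses are complete-case: only respondents with all six dimensions present
enter, and each outcome additionally drops its own missing responses, so
per-outcome denominators may differ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import (
    confint_proportions_2indep,
    proportion_confint,
)

from .outcomes import OUTCOMES
from .scoring import DIMENSIONS, THRESHOLD_MODES, build_profiles, derive_thresholds

logger = logging.getLogger(__name__)

STRATIFIERS = ("cohort", "sex", "ses", "negative_affect_half")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for percentages)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Binomial proportion with Wilson 95% CI, on the percent scale."""

    numerator: int
    denominator: int
    percent: float
    ci_low: float
    ci_high: float

    def display(self) -> str:
        return (
            f"{self.numerator}/{self.denominator} = "
            f"{round_half_away(self.percent):.1f}% "
            f"({round_half_away(self.ci_low):.1f}, {round_half_away(self.ci_high):.1f})"
        )


@dataclass(frozen=True)
class AssociationEstimate:
    """Difference in favorable-outcome prevalence, positive minus not
    positive, in percentage points with a Newcombe 95% CI."""

    dimension: str
    outcome: str
    p_positive: float
    p_negative: float
    n_positive: int
    d_positive: int
    n_negative: int
    d_negative: int
    difference: float
    ci_low: float
    ci_high: float
    adjusted_difference: Optional[float] = None
    adjusted_ci_low: Optional[float] = None
    adjusted_ci_high: Optional[float] = None
    flag: Optional[str] = None


def prevalence(numerator: int, denominator: int) -> PrevalenceEstimate:
    """Proportion with a Wilson score 95% confidence interval."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError(
            f"numerator must be in [0, denominator]; got {numerator}/{denominator}"
        )
    low, high = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
    return PrevalenceEstimate(
        numerator=int(numerator),
        denominator=int(denominator),
        percent=100.0 * numerator / denominator,
        ci_low=100.0 * float(low),
        ci_high=100.0 * float(high),
    )


def prevalence_difference(dimension: str, outcome: str,
                          pos_num: int, pos_den: int,
                          neg_num: int, neg_den: int) -> AssociationEstimate:
    """Difference of two independent proportions with a Newcombe score CI."""
    if pos_den <= 0 or neg_den <= 0:
        raise ValueError("both group denominators must be positive")
    p1 = pos_num / pos_den
    p0 = neg_num / neg_den
    low, high = confint_proportions_2indep(
        pos_num, pos_den, neg_num, neg_den,
        method="newcomb", compare="diff", correction=False,
    )
    return AssociationEstimate(
        dimension=dimension,
        outcome=outcome,
        p_positive=100.0 * p1,
        p_negative=100.0 * p0,
        n_positive=int(pos_num),
        d_positive=int(pos_den),
        n_negative=int(neg_num),
        d_negative=int(neg_den),
        difference=100.0 * (p1 - p0),
        ci_low=100.0 * float(low),
        ci_high=100.0 * float(high),
    )


# ---------------------------------------------------------------------------
# analysis sample and crude associations
# ---------------------------------------------------------------------------

def analysis_mask(profiles: pd.DataFrame) -> pd.Series:
    """Respondents with all six dimensions present (the analytical sample)."""
    return profiles[list(DIMENSIONS)].notna().all(axis=1)


def crude_association_table(profiles: pd.DataFrame,
                            outcomes: pd.DataFrame,
                            dims: Sequence[str] = DIMENSIONS,
                            ) -> list[AssociationEstimate]:
    """Prevalence difference for each dimension x outcome pair, comparing
    respondents positive versus not positive on the dimension."""
    mask = profiles[list(dims)].notna().all(axis=1)
    estimates = []
    for outcome in OUTCOMES:
        ok = mask & outcomes[outcome].notna()
        y = outcomes.loc[ok, outcome].astype(bool)
        for dim in dims:
            d = profiles.loc[ok, dim].astype(bool)
            estimates.append(
                prevalence_difference(
                    dim, outcome,
                    int(y[d].sum()), int(d.sum()),
                    int(y[~d].sum()), int((~d).sum()),
                )
            )
    return estimates


# ---------------------------------------------------------------------------
# mutually adjusted effects via marginal standardization
# ---------------------------------------------------------------------------

def _fit_logit(X: np.ndarray, y: np.ndarray):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    return model.fit(maxiter=100)


def _standardized_differences(result, X: np.ndarray, n_dims: int) -> np.ndarray:
    """Marginal-standardization risk difference (proportion scale) per column.

    Columns 1..n_dims of X are the exposure indicators (column 0 is the
    intercept).  For each, average the predicted probability over the sample
    with that column forced to 1 and to 0, and difference.
    """
    diffs = np.empty(n_dims)
    for j in range(n_dims):
        X1 = X.copy()
        X1[:, j + 1] = 1.0
        X0 = X.copy()
        X0[:, j + 1] = 0.0
        diffs[j] = result.predict(X1).mean() - result.predict(X0).mean()
    return diffs


def adjusted_dimension_effects(profiles: pd.DataFrame, outcomes: pd.DataFrame,
                               n_boot: int = 200, seed: int = 0,
                               dims: Sequence[str] = DIMENSIONS,
                               ) -> list[AssociationEstimate]:
    """Each dimension's effect adjusted for the others, per outcome.

    Fits one additive logistic model per outcome on the complete cases and
    reports marginal-standardization risk differences with percentile
    bootstrap 95% intervals (``n_boot`` resamples of respondents).
    Separation or non-convergence is flagged on the estimate rather than
    raised, since it is a property of the data, not a usage error.
    """
    mask = profiles[list(dims)].notna().all(axis=1)
    rng = np.random.default_rng(seed)
    estimates: list[AssociationEstimate] = []
    crude = {
        (e.dimension, e.outcome): e
        for e in crude_association_table(profiles, outcomes, dims=dims)
    }
    for outcome in OUTCOMES:
        ok = mask & outcomes[outcome].notna()
        y = outcomes.loc[ok, outcome].astype(bool).to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(ok.sum())]
            + [profiles.loc[ok, d].astype(bool).to_numpy(dtype=float) for d in dims]
        )
        flag = None
        try:
            result = _fit_logit(X, y)
            if not result.converged or np.abs(result.params).max() > 15:
                flag = "possible separation or non-convergence"
            point = 100.0 * _standardized_differences(result, X, len(dims))
        except Exception as exc:  # pragma: no cover - defensive
            flag = f"fit failed: {exc}"
            point = np.full(len(dims), np.nan)

        boot = np.full((n_boot, len(dims)), np.nan)
        if flag is None and n_boot > 0:
            n = len(y)
            for b in range(n_boot):
                idx = rng.integers(n, size=n)
                try:
                    res_b = _fit_logit(X[idx], y[idx])
                    boot[b] = 100.0 * _standardized_differences(res_b, X[idx], len(dims))
                except Exception:
                    continue
            lo = np.nanpercentile(boot, 2.5, axis=0)
            hi = np.nanpercentile(boot, 97.5, axis=0)
        elif flag is None:
            lo = np.full(len(dims), np.nan)
            hi = np.full(len(dims), np.nan)
        else:
            logger.warning("adjusted model for %s flagged: %s", outcome, flag)
            lo = np.full(len(dims), np.nan)
            hi = np.full(len(dims), np.nan)

        for j, dim in enumerate(dims):
            estimates.append(
                replace(
                    crude[(dim, outcome)],
                    adjusted_difference=float(point[j]),
                    adjusted_ci_low=float(lo[j]),
                    adjusted_ci_high=float(hi[j]),
                    flag=flag,
                )
            )
    return estimates


# ---------------------------------------------------------------------------
# subgroup stratification and heterogeneity
# ---------------------------------------------------------------------------

def negative_affect_half(records: pd.DataFrame, mask: pd.Series) -> pd.Series:
    """Median split of trait negative affect within the analysis sample.

    Ties at the median go to the "below" group.  Respondents with missing
    affect get a missing stratum label.
    """
    na = records["negative_affect"].astype(float)
    med = na[mask].median()
    half = pd.Series(pd.NA, index=records.index, dtype="string")
    half[na <= med] = "below_median"
    half[na > med] = "above_median"
    half[na.isna()] = pd.NA
    return half


def _stratum_labels(records: pd.DataFrame, variable: str,
                    mask: pd.Series) -> pd.Series:
    if variable == "negative_affect_half":
        return negative_affect_half(records, mask)
    return records[variable].astype("string")


def stratified_analysis(records: pd.DataFrame, profiles: pd.DataFrame,
                        outcomes: pd.DataFrame,
                        variables: Sequence[str] = STRATIFIERS) -> pd.DataFrame:
    """Crude dimension-outcome associations within each stratum, plus a
    heterogeneity (interaction) test per dimension x stratifier x outcome.

    Returns a tidy frame with one row per stratifier x stratum x dimension x
    outcome, including the interaction-term Wald p-value (constant across the
    strata of one stratifier).  Empty strata are skipped with a log entry.
    """
    mask = analysis_mask(profiles)
    rows = []
    for variable in variables:
        labels = _stratum_labels(records, variable, mask)
        levels = sorted(labels.dropna().unique())
        het = _heterogeneity_tests(profiles, outcomes, labels, mask)
        for level in levels:
            in_stratum = mask & (labels == level).fillna(False)
            if not in_stratum.any():
                logger.info("skipping empty stratum %s=%s", variable, level)
                continue
            for outcome in OUTCOMES:
                ok = in_stratum & outcomes[outcome].notna()
                if not ok.any():
                    logger.info(
                        "skipping stratum %s=%s for %s: no responses",
                        variable, level, outcome,
                    )
                    continue
                y = outcomes.loc[ok, outcome].astype(bool)
                for dim in DIMENSIONS:
                    d = profiles.loc[ok, dim].astype(bool)
                    if d.all() or (~d).all():
                        logger.info(
                            "skipping %s in stratum %s=%s: one-sided", dim, variable, level
                        )
                        continue
                    est = prevalence_difference(
                        dim, outcome,
                        int(y[d].sum()), int(d.sum()),
                        int(y[~d].sum()), int((~d).sum()),
                    )
                    rows.append({
                        "stratifier": variable,
                        "stratum": level,
                        "dimension": dim,
                        "outcome": outcome,
                        "n": int(ok.sum()),
                        "difference": est.difference,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "interaction_p": het.get((dim, outcome), np.nan),
                    })
    return pd.DataFrame(rows)


def _heterogeneity_tests(profiles: pd.DataFrame, outcomes: pd.DataFrame,
                         labels: pd.Series, mask: pd.Series) -> dict:
    """Wald p-value of the dimension x stratifier interaction in a logistic
    model, per dimension and outcome (binary stratifiers)."""
    out = {}
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        return out
    for outcome in OUTCOMES:
        ok = mask & outcomes[outcome].notna() & labels.notna()
        y = outcomes.loc[ok, outcome].astype(bool).to_numpy(float)
        s = (labels[ok] == levels[1]).to_numpy(float)
        for dim in DIMENSIONS:
            d = profiles.loc[ok, dim].astype(bool).to_numpy(float)
            X = np.column_stack([np.ones(len(y)), d, s, d * s])
            try:
                res = _fit_logit(X, y)
                out[(dim, outcome)] = float(res.pvalues[3])
            except Exception:
                out[(dim, outcome)] = np.nan
    return out


# ---------------------------------------------------------------------------
# continuum
# ---------------------------------------------------------------------------

def continuum_table(profiles: pd.DataFrame,
                    outcomes: pd.DataFrame) -> pd.DataFrame:
    """Favorable prevalence of each outcome at each dimension count (0-6).

    Levels with no respondents for an outcome are suppressed.  This is the
    graded (continuum) alternative to all-six binary successful aging.
    """
    mask = analysis_mask(profiles)
    rows = []
    counts = profiles.loc[mask, "count"].astype(int)
    for level in range(7):
        at_level = mask & (profiles["count"] == level).fillna(False)
        for outcome in OUTCOMES:
            ok = at_level & outcomes[outcome].notna()
            den = int(ok.sum())
            if den == 0:
                continue
            est = prevalence(int(outcomes.loc[ok, outcome].astype(bool).sum()), den)
            rows.append({
                "count": level,
                "outcome": outcome,
                "numerator": est.numerator,
                "denominator": est.denominator,
                "percent": est.percent,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            })
    return pd.DataFrame(rows)


def count_distribution(records: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Distribution of the dimension count per cohort (analysis sample)."""
    mask = analysis_mask(profiles)
    rows = []
    for cohort, idx in records.loc[mask].groupby("cohort").groups.items():
        counts = profiles.loc[idx, "count"].astype(int)
        n = len(counts)
        for level in range(7):
            k = int((counts == level).sum())
            rows.append({
                "cohort": cohort,
                "count": level,
                "n": k,
                "percent": 100.0 * k / n,
            })
        rows.append({
            "cohort": cohort, "count": "mean", "n": n,
            "percent": float(counts.mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# threshold sensitivity
# ---------------------------------------------------------------------------

def sensitivity_sweep(records: pd.DataFrame,
                      modes: Sequence[str] = THRESHOLD_MODES,
                      outcomes: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Recompute thresholds, profiles and crude associations per mode.

    Returns a tidy comparison with one row per mode x dimension x outcome.
    The positive sets are nested (quintile within quartile within tertile
    within median), so stable signs across modes indicate threshold-robust
    associations.
    """
    from .outcomes import code_outcomes
    from .scoring import standardize_physical

    if outcomes is None:
        outcomes = code_outcomes(records)
    records = standardize_physical(records)
    rows = []
    for mode in modes:
        thresholds = derive_thresholds(records, mode)
        profiles = build_profiles(records, thresholds)
        for est in crude_association_table(profiles, outcomes):
            rows.append({
                "mode": mode,
                "dimension": est.dimension,
                "outcome": est.outcome,
                "difference": est.difference,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p_positive": est.p_positive,
                "p_negative": est.p_negative,
            })
    return pd.DataFrame(rows)
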