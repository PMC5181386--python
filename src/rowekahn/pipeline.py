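"""End-to-end analysis pipeline and report bundle.

``run_pipeline`` executes score -> code -> analyze -> sensitivity on a
participant table and collects tidy tables mirroring the study outputs: a
dimension-prevalence table, outcome prevalences by subgroup, crude and
mutually adjusted dimension-outcome associations, the continuum table (data
behind the prevalence-by-count figure), the count distribution, and the
threshold-sensitivity comparison.  A provenance block (config hash, seed,
versions) accompanies every report; all randomness (the bootstrap) is
seeded, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .analysis import (
    STRATIFIERS,
    adjusted_dimension_effects,
    analysis_mask,
    continuum_table,
    count_distribution,
    crude_association_table,
    prevalence,
    sensitivity_sweep,
    stratified_analysis,
    negative_affect_half,
)
from .codes import CodeRangeSet, default_disease_codes
from .config import COHORTS
from .outcomes import OUTCOMES, code_outcomes
from .scoring import (
    DIMENSIONS,
    THRESHOLD_MODES,
    build_profiles,
    derive_thresholds,
    standardize_physical,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    dimension_prevalence: pd.DataFrame
    outcome_prevalence_by_subgroup: pd.DataFrame
    associations: pd.DataFrame  # crude + adjusted, one row per dim x outcome
    continuum: pd.DataFrame
    count_distribution: pd.DataFrame
    sensitivity: pd.DataFrame
    heterogeneity: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "dimension_prevalence": self.dimension_prevalence,
            "outcome_prevalence_by_subgroup": self.outcome_prevalence_by_subgroup,
            "associations": self.associations,
            "continuum": self.continuum,
            "count_distribution": self.count_distribution,
            "sensitivity": self.sensitivity,
            "heterogeneity": self.heterogeneity,
        }

    def write(self, outdir: str | Path) -> None:
        """One tidy CSV per table plus a JSON bundle with provenance."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle = {"provenance": self.provenance}
        for name, table in self.tables().items():
            table.to_csv(outdir / f"{name}.csv", index=False)
            bundle[name] = table.to_dict(orient="records")
        (outdir / "report.json").write_text(json.dumps(bundle, indent=2, default=str))


def _dimension_prevalence_table(records: pd.DataFrame,
                                profiles: pd.DataFrame) -> pd.DataFrame:
    mask = analysis_mask(profiles)
    rows = []
    for cohort in COHORTS:
        in_c = mask & (records["cohort"] == cohort)
        n = int(in_c.sum())
        for dim in DIMENSIONS:
            k = int(profiles.loc[in_c, dim].astype(bool).sum())
            est = prevalence(k, n)
            rows.append({
                "cohort": cohort, "dimension": dim,
                "n_positive": k, "n": n, "percent": est.percent,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
            })
    return pd.DataFrame(rows)


def _subgroup_outcome_table(records: pd.DataFrame, profiles: pd.DataFrame,
                            outcomes: pd.DataFrame) -> pd.DataFrame:
    mask = analysis_mask(profiles)
    groups: list[tuple[str, str, pd.Series]] = [("overall", "all", mask)]
    for variable in STRATIFIERS:
        if variable == "negative_affect_half":
            labels = negative_affect_half(records, mask)
        else:
            labels = records[variable].astype("string")
        for level in sorted(labels.dropna().unique()):
            groups.append((variable, level, mask & (labels == level).fillna(False)))
    rows = []
    for variable, level, in_g in groups:
        counts = profiles.loc[in_g, "count"].astype(float)
        n_count = len(counts)
        row = {"subgroup": variable, "level": level, "n": int(in_g.sum())}
        for outcome in OUTCOMES:
            ok = in_g & outcomes[outcome].notna()
            den = int(ok.sum())
            if den == 0:
                continue
            est = prevalence(int(outcomes.loc[ok, outcome].astype(bool).sum()), den)
            row[f"{outcome}_n"] = est.numerator
            row[f"{outcome}_den"] = est.denominator
            row[f"{outcome}_pct"] = est.percent
        if n_count:
            se = counts.std(ddof=1) / n_count**0.5 if n_count > 1 else 0.0
            row["mean_count"] = counts.mean()
            row["mean_count_ci_low"] = counts.mean() - 1.96 * se
            row["mean_count_ci_high"] = counts.mean() + 1.96 * se
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(records: pd.DataFrame, *, threshold_mode: str = "tertile",
                 n_boot: int = 200, seed: int = 0,
                 sensitivity_modes: Sequence[str] = THRESHOLD_MODES,
                 code_set: Optional[CodeRangeSet] = None,
                 provenance: Optional[dict] = None) -> AnalysisReport:
    """Run the full analysis on a validated participant table."""
    if code_set is None:
        code_set = default_disease_codes()
    n_input = len(records)
    records = standardize_physical(records)
    thresholds = derive_thresholds(records, threshold_mode)
    profiles = build_profiles(records, thresholds, code_set)
    outcomes = code_outcomes(records)
    mask = analysis_mask(profiles)
    n_analysis = int(mask.sum())
    logger.info(
        "analysis sample: %d of %d respondents (%d excluded with >=1 missing dimension)",
        n_analysis, n_input, n_input - n_analysis,
    )
    if n_analysis == 0:
        raise ValueError(
            "analysis sample is empty after complete-case exclusion on the six dimensions"
        )

    adjusted = adjusted_dimension_effects(profiles, outcomes, n_boot=n_boot, seed=seed)
    associations = pd.DataFrame([
        {
            "dimension": e.dimension, "outcome": e.outcome,
            "p_positive": e.p_positive, "p_negative": e.p_negative,
            "n_positive": e.n_positive, "d_positive": e.d_positive,
            "n_negative": e.n_negative, "d_negative": e.d_negative,
            "difference": e.difference, "ci_low": e.ci_low, "ci_high": e.ci_high,
            "adjusted_difference": e.adjusted_difference,
            "adjusted_ci_low": e.adjusted_ci_low,
            "adjusted_ci_high": e.adjusted_ci_high,
            "flag": e.flag,
        }
        for e in adjusted
    ])

    strat = stratified_analysis(records, profiles, outcomes)

    report = AnalysisReport(
        dimension_prevalence=_dimension_prevalence_table(records, profiles),
        outcome_prevalence_by_subgroup=_subgroup_outcome_table(records, profiles, outcomes),
        associations=associations,
        continuum=continuum_table(profiles, outcomes),
        count_distribution=count_distribution(records, profiles),
        sensitivity=sensitivity_sweep(records, sensitivity_modes, outcomes),
        heterogeneity=strat,
        provenance={
            "package_version": __version__,
            "threshold_mode": threshold_mode,
            "n_boot": n_boot,
            "seed": seed,
            "n_input": n_input,
            "n_analysis": n_analysis,
            **(provenance or {}),
        },
    )
    return report
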