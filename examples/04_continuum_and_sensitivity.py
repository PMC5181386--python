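"""The successful-aging continuum and threshold-sensitivity analysis.

The continuum table gives the favorable prevalence of each outcome at each
dimension count 0-6; the sensitivity sweep recomputes thresholds, profiles
and crude associations under quartile, quintile and median cutoffs to check
the conclusions are not an artifact of the tertile choice.
"""

import numpy as np

from rowekahn import (
    SimulationConfig, build_profiles, code_outcomes, continuum_table,
    derive_thresholds, generate_cohorts, sensitivity_sweep, standardize_physical,
)

records = standardize_physical(generate_cohorts(SimulationConfig(seed=20)))
profiles = build_profiles(records, derive_thresholds(records, "tertile"))
outcomes = code_outcomes(records)

table = continuum_table(profiles, outcomes)
print("favorable prevalence (%) by number of positive dimensions:")
wide = table.pivot(index="count", columns="outcome", values="percent")
print(wide.round(1).to_string())

sweep = sensitivity_sweep(records)
stable = sweep.groupby(["dimension", "outcome"])["difference"].apply(
    lambda s: (np.sign(s) == np.sign(s.iloc[0])).all()
)
print(f"\nassociation signs stable across all threshold modes: "
      f"{int(stable.sum())}/{len(stable)} dimension-outcome pairs")
# Prevalence rising steadily with the count — well before all six
# dimensions are positive — supports treating successful aging as a
# continuum rather than a pass/fail state.
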