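import pandas as pd
import pytest

from rowekahn import (
    SimulationConfig,
    build_profiles,
    code_outcomes,
    derive_thresholds,
    generate_cohorts,
    standardize_physical,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def records(default_config) -> pd.DataFrame:
    """One default-sized synthetic two-cohort sample, standardized."""
    return standardize_physical(generate_cohorts(default_config))


@pytest.fixture(scope="session")
def thresholds(records):
    return derive_thresholds(records, "tertile")


@pytest.fixture(scope="session")
def profiles(records, thresholds) -> pd.DataFrame:
    return build_profiles(records, thresholds)


@pytest.fixture(scope="session")
def outcomes(records) -> pd.DataFrame:
    return code_outcomes(records)


@pytest.fixture(scope="session")
def small_records() -> pd.DataFrame:
    """A smaller sample for the slower model-based tests."""
    cfg = SimulationConfig(n_young=400, n_old=250, seed=11)
    return standardize_physical(generate_cohorts(cfg))
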