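import numpy as np
import pandas as pd
import pytest

from rowekahn import (
    build_profile,
    build_profiles,
    default_disease_codes,
    derive_thresholds,
    generate_cohorts,
    inject_missingness,
    standardize_physical,
    SimulationConfig,
)
from rowekahn.config import INTERPERSONAL_ITEMS, PRODUCTIVE_ITEMS
from rowekahn.scoring import (
    DIMENSIONS,
    CohortThresholds,
    ThresholdError,
    ThresholdSet,
    classify_cognitive,
    classify_interpersonal,
    classify_no_disability,
    classify_physical,
    classify_productive,
    _grid_cutoff,
)


def _published(records):
    return derive_thresholds(records, "published")


@pytest.fixture(scope="module")
def published(records):
    return _published(records)


class TestScalarClassifiers:
    def test_disability_boundaries(self, published):
        assert classify_no_disability(0.5, "1932", published) is True
        assert classify_no_disability(0.1, "1952", published) is False
        assert classify_no_disability(0.0, "1952", published) is True
        assert classify_no_disability(0.0, "1932", published) is True

    def test_negative_disability_rejected(self, published):
        with pytest.raises(ValueError, match="nonnegative"):
            classify_no_disability(-0.5, "1952", published)

    def test_disability_missing_propagates(self, published):
        assert classify_no_disability(float("nan"), "1952", published) is pd.NA

    def test_cognition_boundaries(self, published):
        assert classify_cognitive(41, "1952", published) is True
        assert classify_cognitive(40, "1952", published) is False
        assert classify_cognitive(31, "1932", published) is True
        assert classify_cognitive(30, "1932", published) is False

    def test_interpersonal_requires_all_three(self, published):
        assert classify_interpersonal((True, True, True), published) is True
        assert classify_interpersonal((True, True, False), published) is False
        assert classify_interpersonal((False, False, False), published) is False
        assert classify_interpersonal((True, pd.NA, True), published) is pd.NA

    def test_productive_cohort_cutoffs(self, published):
        two = (True, True, False, False, False)
        assert classify_productive(two, "1932", published) is True
        assert classify_productive(two, "1952", published) is False
        assert classify_productive((True,) * 5, "1952", published) is True
        assert classify_productive((True,) * 5, "1932", published) is True

    def test_physical_three_of_four_strict_medians(self, published):
        t = published["1952"]
        g, f = t.grip_median["female"], t.fev1_median["female"]
        s, p = t.sbp_median, t.pulse_median
        args = dict(cohort="1952", sex="female", thresholds=published)
        assert classify_physical(g + 1, f + 1, s - 1, p - 1, **args) is True
        # exactly two favorable is not enough
        assert classify_physical(g + 1, f + 1, s + 1, p + 1, **args) is False
        # a value exactly at the median counts as unfavorable
        assert classify_physical(g, f + 1, s - 1, p, **args) is False
        assert classify_physical(g + 1, f + 1, s - 1, p, **args) is True
        assert classify_physical(np.nan, f + 1, s - 1, p - 1, **args) is pd.NA


class TestStandardizePhysical:
    def _stratum(self, heights, grips):
        n = len(heights)
        return pd.DataFrame({
            "cohort": ["1952"] * n, "sex": ["female"] * n,
            "height": heights, "grip": grips, "fev1": [2.5] * n,
        })

    def test_exact_line_fit_gives_zero_residuals(self):
        out = standardize_physical(self._stratum([150, 160, 170], [20, 25, 30]))
        assert np.allclose(out["std_grip"], 0.0, atol=1e-10)

    def test_constant_height_centers_on_stratum_mean(self):
        out = standardize_physical(self._stratum([160, 160, 160], [20, 25, 30]))
        assert np.allclose(out["std_grip"], [-5.0, 0.0, 5.0])

    def test_residuals_mean_zero_within_stratum(self, records):
        for (_, _), idx in records.groupby(["cohort", "sex"]).groups.items():
            assert abs(records.loc[idx, "std_grip"].mean()) < 1e-8
            assert abs(records.loc[idx, "std_fev1"].mean()) < 1e-8

    def test_small_stratum_error_names_stratum(self):
        df = self._stratum([150, 160], [20, 25])
        df.loc[1, "grip"] = np.nan
        with pytest.raises(ThresholdError, match="cohort=1952 sex=female"):
            standardize_physical(df)


class TestDeriveThresholds:
    def test_median_mode_on_symmetric_grid(self):
        values = np.arange(1, 11, dtype=float)
        cutoff, frac = _grid_cutoff(values, 0.5, "high")
        assert frac == 0.5
        assert cutoff == 6.0  # values >= 6 are exactly half

    def test_zero_inflated_tertile_picks_zero_mass(self):
        # 81% zeros: the zero cutoff's positive fraction (0.81) is still the
        # closest achievable to 1/3 from the observed grid's lower end
        values = np.r_[np.zeros(81), np.full(19, 2.0)]
        cutoff, frac = _grid_cutoff(values, 1 / 3, "low")
        assert cutoff == 0.0
        assert frac == 0.81

    def test_tertile_matches_published_cutoffs_on_default_data(self, records):
        empirical = derive_thresholds(records, "tertile")
        published = derive_thresholds(records, "published")
        for cohort in ("1952", "1932"):
            e, p = empirical[cohort], published[cohort]
            assert e.opcs_cutoff == p.opcs_cutoff
            # the integer cognition grid admits one step of sampling noise
            # around the published approximate-tertile boundary
            assert abs(e.ah4_cutoff - p.ah4_cutoff) <= 1
            assert e.productive_min == p.productive_min
            assert e.interpersonal_min == p.interpersonal_min == 3

    def test_published_preset_values(self, published):
        assert published["1952"].opcs_cutoff == 0.0
        assert published["1932"].opcs_cutoff == 0.5
        assert published["1952"].ah4_cutoff == 41
        assert published["1932"].ah4_cutoff == 31
        assert published["1952"].productive_min == 3
        assert published["1932"].productive_min == 2

    def test_empty_cohort_rejected(self, records):
        with pytest.raises(ThresholdError, match="1932"):
            derive_thresholds(records[records["cohort"] == "1952"])

    def test_unknown_mode_rejected(self, records):
        with pytest.raises(ThresholdError, match="decile"):
            derive_thresholds(records, "decile")


class TestProfiles:
    def test_count_identity_and_all_six(self, profiles):
        present = profiles[list(DIMENSIONS)].notna().all(axis=1)
        summed = profiles.loc[present, list(DIMENSIONS)].astype(int).sum(axis=1)
        assert (profiles.loc[present, "count"].astype(int) == summed).all()
        assert (
            (profiles.loc[present, "all_six"].astype(bool))
            == (profiles.loc[present, "count"] == 6)
        ).all()
        assert profiles.loc[~present, "count"].isna().all()
        assert profiles.loc[~present, "all_six"].isna().all()
        assert profiles["count"].dropna().between(0, 6).all()

    def test_missing_component_makes_dimension_and_count_missing(
        self, records, thresholds
    ):
        df = records.head(5).copy()
        df["ah4_score"] = pd.NA
        prof = build_profiles(df, thresholds)
        assert prof["cognitive_good"].isna().all()
        assert prof["count"].isna().all()
        assert prof["all_six"].isna().all()
        assert prof["disease_free"].notna().all()  # other dimensions unaffected

    def test_order_invariance(self, records, thresholds):
        shuffled = records.sample(frac=1, random_state=3)
        prof = build_profiles(records, thresholds)
        prof_shuffled = build_profiles(shuffled, thresholds)
        pd.testing.assert_frame_equal(prof_shuffled.sort_index(), prof)

    def test_scalar_profile_examples(self, published):
        t = published["1952"]
        base = {
            "cohort": "1952", "sex": "male",
            "rcgp_codes": [], "opcs_score": 0.0, "ah4_score": 50,
            "std_grip": t.grip_median["male"] + 1,
            "std_fev1": t.fev1_median["male"] + 1,
            "sbp": t.sbp_median - 1, "pulse": t.pulse_median - 1,
            **{k: True for k in INTERPERSONAL_ITEMS},
            **{k: True for k in PRODUCTIVE_ITEMS},
        }
        full = build_profile(base, published)
        assert full["count"] == 6 and full["all_six"] is True

        missing_ah4 = build_profile({**base, "ah4_score": np.nan}, published)
        assert missing_ah4["count"] is pd.NA and missing_ah4["all_six"] is pd.NA

        only_disease_free = build_profile(
            {
                **base, "opcs_score": 3.0, "ah4_score": 0,
                "std_grip": t.grip_median["male"] - 1,
                "std_fev1": t.fev1_median["male"] - 1,
                "sbp": t.sbp_median + 1, "pulse": t.pulse_median + 1,
                **{k: False for k in INTERPERSONAL_ITEMS},
                **{k: False for k in PRODUCTIVE_ITEMS},
            },
            published,
        )
        assert only_disease_free["count"] == 1
        assert only_disease_free["disease_free"] is True

    def test_vectorized_profiles_match_bruteforce_oracle(self, records, thresholds):
        """On small instances the vectorized scorer must agree with a literal
        per-rule reimplementation of the dimension definitions."""
        sample = records.sample(12, random_state=1)
        sample = inject_missingness(sample, 0.15, seed=2)
        sample = sample.assign(
            std_grip=records.loc[sample.index, "std_grip"],
            std_fev1=records.loc[sample.index, "std_fev1"],
        )
        got = build_profiles(sample, thresholds)
        code_set = default_disease_codes()
        for idx, row in sample.iterrows():
            expected = _oracle_profile(row, thresholds, code_set)
            for key, want in expected.items():
                have = got.loc[idx, key]
                if want is None:
                    assert pd.isna(have), (idx, key)
                else:
                    assert have == want, (idx, key)

    def test_threshold_nesting_across_modes(self, records):
        """Positive sets nest: quintile within quartile within tertile within
        median, for every score-based dimension."""
        modes = ["quintile", "quartile", "tertile", "median"]
        profs = {m: build_profiles(records, derive_thresholds(records, m)) for m in modes}
        for narrow, wide in zip(modes, modes[1:]):
            for dim in DIMENSIONS:
                if dim == "physical_good":
                    continue  # medians are mode-invariant by construction
                a = profs[narrow][dim].fillna(False).astype(bool)
                b = profs[wide][dim].fillna(False).astype(bool)
                assert (b | ~a).all(), (narrow, wide, dim)


def _oracle_profile(row, thresholds, code_set):
    """Literal restatement of the dimension rules, one condition at a time."""

    def miss(*values):
        return any(pd.isna(v) for v in values)

    t = thresholds[row["cohort"]]
    out = {}

    codes = row["rcgp_codes"]
    if not isinstance(codes, (list, tuple)):
        out["disease_free"] = None
    else:
        out["disease_free"] = all(c not in code_set for c in codes)

    out["no_disability"] = (
        None if miss(row["opcs_score"]) else row["opcs_score"] <= t.opcs_cutoff
    )
    out["cognitive_good"] = (
        None if miss(row["ah4_score"]) else row["ah4_score"] >= t.ah4_cutoff
    )

    if miss(row["std_grip"], row["std_fev1"], row["sbp"], row["pulse"]):
        out["physical_good"] = None
    else:
        favorable = 0
        if row["std_grip"] > t.grip_median[row["sex"]]:
            favorable += 1
        if row["std_fev1"] > t.fev1_median[row["sex"]]:
            favorable += 1
        if row["sbp"] < t.sbp_median:
            favorable += 1
        if row["pulse"] < t.pulse_median:
            favorable += 1
        out["physical_good"] = favorable >= 3

    inter = [row[k] for k in INTERPERSONAL_ITEMS]
    out["interpersonal_good"] = (
        None if miss(*inter) else sum(map(bool, inter)) >= t.interpersonal_min
    )
    prod = [row[k] for k in PRODUCTIVE_ITEMS]
    out["productive_good"] = (
        None if miss(*prod) else sum(map(bool, prod)) >= t.productive_min
    )

    if any(v is None for v in out.values()):
        out["count"] = None
        out["all_six"] = None
    else:
        out["count"] = sum(map(int, out.values()))
        out["all_six"] = out["count"] == 6
    return out
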