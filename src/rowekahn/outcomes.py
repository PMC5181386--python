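"""Dichotomization of the four self-rated health and satisfaction outcomes.

Two four-level global health ratings (recent health; health for age) are
coded favorable when excellent or good, unfavorable when fair or poor.  Two
seven-point satisfaction scales (health; life), with 7 the most positive,
are coded favorable for the three most positive responses (5-7); the neutral
midpoint (4) and the three most negative responses are unfavorable.
Missing responses propagate.
"""

from __future__ import annotations

import pandas as pd

from .config import FOUR_LEVELS

#: raw response field -> coded outcome column
OUTCOME_MAP = {
    "srh_recent": "recent_good",
    "srh_for_age": "for_age_good",
    "sat_health": "health_satisfied",
    "sat_life": "life_satisfied",
}
OUTCOMES = tuple(OUTCOME_MAP.values())

_FAVORABLE_FOUR = {"excellent", "good"}


def _is_missing(value) -> bool:
    return value is None or value is pd.NA or (
        isinstance(value, float) and value != value
    )


def code_four_level(response):
    """Favorable iff excellent or good (vs fair or poor)."""
    if _is_missing(response):
        return pd.NA
    if response not in FOUR_LEVELS:
        raise ValueError(
            f"unknown four-level response {response!r}; expected one of {FOUR_LEVELS}"
        )
    return response in _FAVORABLE_FOUR


def code_seven_point(response):
    """Favorable iff in the three most positive levels (5-7 of 1-7)."""
    if _is_missing(response):
        return pd.NA
    value = int(response)
    if value != response or not 1 <= value <= 7:
        raise ValueError(f"seven-point response must be an integer in 1..7, got {response!r}")
    return value >= 5


def code_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Code all four outcomes for a participant table.

    Returns nullable-boolean columns recent_good, for_age_good,
    health_satisfied, life_satisfied indexed like ``records``.
    """
    out = pd.DataFrame(index=records.index)
    for raw, coded in OUTCOME_MAP.items():
        coder = code_four_level if raw.startswith("srh") else code_seven_point
        out[coded] = pd.array([coder(v) for v in records[raw]], dtype="boolean")
    return out
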