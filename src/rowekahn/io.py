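"""Participant CSV schema: reading, writing and validation.

One row per respondent, columns exactly the participant fields.  Booleans are
written as 1/0, morbidity codes as a semicolon-delimited string ("-" for an
empty code list), and missing values as empty cells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .codes import CodeParseError, _parse_code
from .config import COHORTS, FOUR_LEVELS, SES_LEVELS, SEXES
from .simulate import PARTICIPANT_COLUMNS

_BOOL_COLUMNS = [
    "lives_with_partner", "contact_4wk", "club_attendance",
    "work_training", "voluntary_work", "childcare", "support_other",
    "group_member",
]
_INT_COLUMNS = ["ah4_score", "sat_health", "sat_life"]
_FLOAT_COLUMNS = ["height", "grip", "fev1", "sbp", "pulse", "opcs_score",
                  "negative_affect"]
_POSITIVE_COLUMNS = ["height", "grip", "fev1", "sbp", "pulse"]

_NO_CODES = "-"


class SchemaError(ValueError):
    """Raised when a participant table violates the documented schema."""


def write_participants(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()[PARTICIPANT_COLUMNS]
    out["rcgp_codes"] = [
        np.nan if not isinstance(v, (list, tuple)) else (";".join(v) or _NO_CODES)
        for v in out["rcgp_codes"]
    ]
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype("boolean").astype("Int64")
    out.to_csv(path, index=False)


def _parse_codes_cell(value, row: int) -> list[str] | float:
    if pd.isna(value) or value == "":
        return np.nan
    if value == _NO_CODES:
        return []
    codes = [c.strip() for c in str(value).split(";") if c.strip()]
    for c in codes:
        try:
            _parse_code(c)
        except CodeParseError as exc:
            raise SchemaError(f"row {row}, column rcgp_codes: {exc}") from exc
    return codes


def read_participants(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cohort": str})
    missing_cols = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {missing_cols}")
    df["rcgp_codes"] = [
        _parse_codes_cell(v, i) for i, v in enumerate(df["rcgp_codes"])
    ]
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype("Int64").astype("boolean")
    for col in _INT_COLUMNS:
        df[col] = df[col].astype("Int64")
    df = df[PARTICIPANT_COLUMNS]
    if validate:
        validate_participants(df)
    return df


def validate_participants(records: pd.DataFrame) -> None:
    """Check the participant table against the documented schema.

    Raises :class:`SchemaError` naming the first offending row and column.
    """

    def _bad(column: str, mask: pd.Series, message: str) -> None:
        mask = mask.fillna(False)
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise SchemaError(f"row {row}, column {column}: {message}")

    _bad("cohort", ~records["cohort"].isin(COHORTS), f"must be one of {COHORTS}")
    _bad("cohort", records["cohort"].isna(), "must not be missing")
    _bad("sex", ~records["sex"].isin(SEXES) & records["sex"].notna(),
         f"must be one of {SEXES}")
    _bad("ses", ~records["ses"].isin(SES_LEVELS) & records["ses"].notna(),
         f"must be one of {SES_LEVELS}")
    for col in _POSITIVE_COLUMNS:
        _bad(col, records[col] <= 0, "must be positive")
    _bad("opcs_score", records["opcs_score"] < 0, "must be nonnegative")
    _bad("ah4_score", records["ah4_score"] < 0, "must be nonnegative")
    for col in ("srh_recent", "srh_for_age"):
        _bad(col, ~records[col].isin(FOUR_LEVELS) & records[col].notna(),
             f"must be one of {FOUR_LEVELS}")
    for col in ("sat_health", "sat_life"):
        _bad(col, (records[col] < 1) | (records[col] > 7),
             "must be an integer in 1..7")
    for i, v in enumerate(records["rcgp_codes"]):
        if isinstance(v, (list, tuple)):
            for c in v:
                try:
                    _parse_code(c)
                except CodeParseError as exc:
                    raise SchemaError(f"row {i}, column rcgp_codes: {exc}") from exc
        elif not (isinstance(v, float) and np.isnan(v)):
            raise SchemaError(
                f"row {i}, column rcgp_codes: expected list of codes or missing"
            )
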