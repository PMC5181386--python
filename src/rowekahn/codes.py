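"""Morbidity code-range parsing and membership.

Chronic-disease status is flagged from Royal College of General Practitioners
(RCGP) morbidity codes: a respondent is disease-free when none of their codes
falls inside a configured set of 4-digit code ranges covering the common
age-associated chronic diseases (coronary heart disease, stroke, COPD,
non-skin cancer, diabetes, Parkinson's, serious mental health problems).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

# Qualifying-disease code ranges; inclusive at both ends, with the skin-cancer
# code 0455 carved out of the cancer block.
DISEASE_CODE_SPEC = (
    "0400-0540 (excluding 0455), 0720, 1000, 1015-1030, 1205, 1315, "
    "1940-1950, 2100-2115, 2420, 2490-2510"
)


class CodeParseError(ValueError):
    """Raised when a code-range specification or a code is malformed."""


_CODE_RE = re.compile(r"^\d{4}$")
_PART_RE = re.compile(
    r"^\s*(?P<lo>\S+?)\s*(?:[-–]\s*(?P<hi>\S+?))?\s*"
    r"(?:\(\s*excluding\s+(?P<excl>[^)]*)\))?\s*$"
)


def _parse_code(token: str) -> int:
    token = token.strip()
    if not _CODE_RE.match(token):
        raise CodeParseError(f"malformed 4-digit code: {token!r}")
    return int(token)


@dataclass(frozen=True)
class CodeRangeSet:
    """Membership predicate over 4-digit codes defined by inclusive ranges
    minus explicit exclusions."""

    ranges: tuple[tuple[int, int], ...]
    exclusions: frozenset[int] = field(default_factory=frozenset)

    def __contains__(self, code: str | int) -> bool:
        value = _parse_code(code) if isinstance(code, str) else int(code)
        if value in self.exclusions:
            return False
        return any(lo <= value <= hi for lo, hi in self.ranges)

    def members(self) -> list[str]:
        """All member codes, zero-padded, sorted."""
        out = {
            v
            for lo, hi in self.ranges
            for v in range(lo, hi + 1)
            if v not in self.exclusions
        }
        return [f"{v:04d}" for v in sorted(out)]


def parse_code_ranges(spec: str) -> CodeRangeSet:
    """Parse a comma-separated list of 4-digit codes and inclusive ranges.

    Ranges use ``lo-hi`` (hyphen or en-dash); an optional trailing
    ``(excluding C1, C2, ...)`` removes individual codes from the preceding
    range.  Example: ``"0400-0540 (excluding 0455), 0720"``.
    """
    ranges: list[tuple[int, int]] = []
    exclusions: set[int] = set()
    # split on commas that are not inside an (excluding ...) group
    for part in re.split(r",(?![^(]*\))", spec):
        if not part.strip():
            continue
        m = _PART_RE.match(part)
        if m is None:
            raise CodeParseError(f"malformed code-range token: {part.strip()!r}")
        lo = _parse_code(m.group("lo"))
        hi = _parse_code(m.group("hi")) if m.group("hi") else lo
        if hi < lo:
            raise CodeParseError(f"descending range: {part.strip()!r}")
        ranges.append((lo, hi))
        if m.group("excl"):
            for token in m.group("excl").split(","):
                excl = _parse_code(token)
                if not lo <= excl <= hi:
                    raise CodeParseError(
                        f"exclusion {token.strip()!r} outside range {lo:04d}-{hi:04d}"
                    )
                exclusions.add(excl)
    return CodeRangeSet(ranges=tuple(ranges), exclusions=frozenset(exclusions))


def default_disease_codes() -> CodeRangeSet:
    """The default qualifying chronic-disease code set."""
    return parse_code_ranges(DISEASE_CODE_SPEC)
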