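"""ICD-10-AM code normalization and pattern matching.

Diagnosis lists in the condition registry use a compact dialect of
comma-separated tokens:

* a bare code is an *exact-prefix* pattern: ``J45`` matches ``J45``,
  ``J450`` and ``J45.0``; ``K528`` matches only the K52.8 family; the
  single letter ``J`` matches the whole respiratory chapter;
* ``A-B`` is a *range* over three-character categories: ``J09-J13``
  matches any code whose category falls between J09 and J13 inclusive;
* range endpoints written with a single digit are zero-padded to a
  category (``A0-A9`` means categories A00 through A09 — the decade —
  not A00 through A99, which would swallow A15-A19 tuberculosis codes).

Codes are normalized by upper-casing and stripping dots and whitespace
before matching, so ``j45.0`` and ``J450`` are equivalent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_CODE_RE = re.compile(r"^[A-Z][0-9A-Z]{0,4}$")
_ENDPOINT_RE = re.compile(r"^([A-Z])(\d{1,2})$")


class IcdPatternError(ValueError):
    """Raised for a malformed token in a diagnosis-pattern string."""


def normalize_code(code: str) -> str:
    """Uppercase and remove dots/whitespace from an ICD-10 code string."""
    return code.replace(".", "").replace(" ", "").strip().upper()


@dataclass(frozen=True)
class IcdPattern:
    """A single matching rule: either an exact prefix or a category range."""

    kind: str  # "prefix" | "range"
    lo: str
    hi: str

    @property
    def specificity(self) -> int:
        """Length of the matched prefix; ranges match at category (3) level."""
        return len(self.lo) if self.kind == "prefix" else 3

    def matches(self, code: str) -> bool:
        """Test a *normalized* code against this pattern."""
        if self.kind == "prefix":
            return code.startswith(self.lo)
        category = code[:3]
        return len(code) >= 3 and self.lo <= category <= self.hi


def _parse_endpoint(token: str, raw: str) -> str:
    m = _ENDPOINT_RE.match(token)
    if not m:
        raise IcdPatternError(
            f"range endpoint {token!r} in {raw!r} is not letter+digits"
        )
    letter, digits = m.groups()
    return f"{letter}{int(digits):02d}"


def parse_icd_patterns(spec_text: str) -> list[IcdPattern]:
    """Parse a comma-separated diagnosis-pattern string.

    Returns an empty list for empty input.  Raises :class:`IcdPatternError`
    for malformed tokens (empty range sides, cross-letter ranges, invalid
    characters).
    """
    patterns: list[IcdPattern] = []
    for raw in spec_text.split(","):
        token = normalize_code(raw)
        if not token:
            continue  # blank segment (empty input, trailing comma)
        if "-" in token:
            sides = token.split("-")
            if len(sides) != 2 or not sides[0] or not sides[1]:
                raise IcdPatternError(f"malformed range token {raw.strip()!r}")
            lo = _parse_endpoint(sides[0], raw.strip())
            hi = _parse_endpoint(sides[1], raw.strip())
            if lo[0] != hi[0]:
                raise IcdPatternError(
                    f"range {raw.strip()!r} crosses letter blocks ({lo[0]}-{hi[0]})"
                )
            if lo > hi:
                raise IcdPatternError(f"range {raw.strip()!r} has lo > hi")
            patterns.append(IcdPattern(kind="range", lo=lo, hi=hi))
        else:
            if not _CODE_RE.match(token):
                raise IcdPatternError(f"invalid code token {raw.strip()!r}")
            patterns.append(IcdPattern(kind="prefix", lo=token, hi=token))
    return patterns


def all_categories() -> list[str]:
    """All 2600 three-character ICD-10 categories A00..Z99."""
    return [
        f"{letter}{i:02d}"
        for letter in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for i in range(100)
    ]


def expand_pattern(pattern: IcdPattern) -> list[str]:
    """Concrete category-level (or finer) codes covered by one pattern.

    Exact prefixes of three or more characters stand for themselves; shorter
    prefixes are expanded over the category axis.  Used by the synthetic
    register generator to draw representative codes.
    """
    if pattern.kind == "prefix":
        if len(pattern.lo) >= 3:
            return [pattern.lo]
        return [c for c in all_categories() if c.startswith(pattern.lo)]
    letter = pattern.lo[0]
    lo_n, hi_n = int(pattern.lo[1:]), int(pattern.hi[1:])
    return [f"{letter}{i:02d}" for i in range(lo_n, hi_n + 1)]
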