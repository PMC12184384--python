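"""Partial calendar-date tokens.

Spontaneous-report databases carry dates as numeric tokens of varying
completeness: ``YYYYMMDD``, ``YYYYMM`` or bare ``YYYY``.  Downstream rules
depend on the *precision* of a token (time-to-onset only accepts
day-precision dates), so parsing keeps the precision explicit instead of
silently filling in missing components.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Precision(str, Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"


_SEPARATORS = re.compile(r"[/\-.]")


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date known to day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.year <= 9999):
            raise ValueError(f"year out of range: {self.year}")
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # validates day-of-month (raises ValueError for e.g. Feb 30)
            _dt.date(self.year, self.month, self.day)

    @property
    def precision(self) -> Precision:
        if self.day is not None:
            return Precision.DAY
        if self.month is not None:
            return Precision.MONTH
        return Precision.YEAR

    def as_date(self) -> _dt.date:
        """Exact date; only defined for day-precision tokens."""
        if self.precision is not Precision.DAY:
            raise ValueError(f"not a day-precision date: {self}")
        return _dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        """Total order for versioning comparisons; missing parts sort low."""
        return (self.year, self.month or 0, self.day or 0)

    def token(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.token()


def parse_date_token(token: object) -> Optional[PartialDate]:
    """Parse a raw date field into a :class:`PartialDate`.

    Accepts ``YYYYMMDD`` / ``YYYYMM`` / ``YYYY`` digit strings (the FAERS
    convention) and separator-delimited forms like ``2020/01/05`` (seen in
    JADER extracts).  Returns ``None`` for empty or unparseable tokens —
    missingness is a normal state here, not an error.
    """
    if token is None:
        return None
    text = str(token).strip()
    if not text or text.lower() in {"nan", "none", "na"}:
        return None
    if text.endswith(".0"):  # pandas float round-trip of numeric columns
        text = text[:-2]
    text = _SEPARATORS.sub("", text)
    if not text.isdigit():
        return None
    try:
        if len(text) == 8:
            return PartialDate(int(text[:4]), int(text[4:6]), int(text[6:8]))
        if len(text) == 6:
            return PartialDate(int(text[:4]), int(text[4:6]))
        if len(text) == 4:
            return PartialDate(int(text))
    except ValueError:
        return None
    return None


#: sort key for absent dates — any dated version outranks an undated one
MISSING_DATE_KEY = (0, 0, 0)


def date_sort_key(date: Optional[PartialDate]) -> tuple[int, int, int]:
    return MISSING_DATE_KEY if date is None else date.sort_key()
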