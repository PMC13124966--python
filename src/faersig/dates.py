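"""Partial-precision FAERS dates.

FAERS encodes dates as YYYYMMDD integers but frequently carries only
YYYYMM or YYYY. Dates are kept as strings throughout the data model
("" = missing); this module is the single place that interprets them.
Downstream rules (timeline plausibility, time-to-onset) only ever act
on full-precision dates — a partial date is *unknown at day level*,
never coerced to a day.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

FULL = "day"
MONTH = "month"
YEAR = "year"
MISSING = "missing"


def precision(value: str) -> str:
    """Precision class of a raw date string: day, month, year or missing."""
    s = (value or "").strip()
    if not s:
        return MISSING
    if len(s) == 8 and s.isdigit():
        return FULL
    if len(s) == 6 and s.isdigit():
        return MONTH
    if len(s) == 4 and s.isdigit():
        return YEAR
    return MISSING


def is_full(value: str) -> bool:
    return precision(value) == FULL


def to_date(value: str) -> _dt.date | None:
    """Parse a full-precision YYYYMMDD string; None for partial/missing/invalid."""
    if not is_full(value):
        return None
    try:
        return _dt.datetime.strptime(value.strip(), "%Y%m%d").date()
    except ValueError:
        return None


def days_between(later: str, earlier: str) -> int | None:
    """Calendar-day difference later − earlier; None unless both full-precision."""
    a, b = to_date(later), to_date(earlier)
    if a is None or b is None:
        return None
    return (a - b).days


def shift_days(value: str, days: int) -> str:
    d = to_date(value)
    if d is None:
        raise ValueError(f"cannot shift partial/missing date {value!r}")
    return (d + _dt.timedelta(days=int(days))).strftime("%Y%m%d")


def full_mask(series: pd.Series) -> pd.Series:
    """Boolean mask of entries parseable as full YYYYMMDD dates."""
    s = series.fillna("").astype(str).str.strip()
    return (s.str.len() == 8) & s.str.isdigit()


def to_datetime(series: pd.Series) -> pd.Series:
    """Vectorised parse; partial/missing entries become NaT."""
    s = series.fillna("").astype(str).str.strip()
    out = pd.to_datetime(s.where(full_mask(series), None), format="%Y%m%d", errors="coerce")
    return out


def days_between_series(later: pd.Series, earlier: pd.Series) -> pd.Series:
    """Vectorised day difference; NaN where either side is not full-precision."""
    delta = to_datetime(later) - to_datetime(earlier)
    return delta.dt.days.astype(float)


def int_dates_to_str(values: np.ndarray) -> np.ndarray:
    """Render integer YYYYMMDD values as the canonical string form."""
    return np.char.mod("%d", values.astype(np.int64))
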