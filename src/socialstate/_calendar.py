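"""Integer-day calendar helpers.

All simulation and preprocessing time arithmetic runs on integer days since
2000-01-01 so that ISO-8601 dates in the CSV bundle round-trip exactly.
Ages are expressed in fractional years using the mean Gregorian year length.
"""

from __future__ import annotations

import datetime as _dt

EPOCH = _dt.date(2000, 1, 1)
DAYS_PER_YEAR = 365.25


def day_to_iso(day: int) -> str:
    """Convert an integer day offset from the epoch to an ISO-8601 date string."""
    return (EPOCH + _dt.timedelta(days=int(day))).isoformat()


def iso_to_day(iso: str) -> int:
    """Convert an ISO-8601 date string to an integer day offset from the epoch."""
    return (_dt.date.fromisoformat(str(iso)) - EPOCH).days


def years_between(day_from: int, day_to: int) -> float:
    """Elapsed time in fractional years between two day offsets."""
    return (day_to - day_from) / DAYS_PER_YEAR
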