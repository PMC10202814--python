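"""Calendar arithmetic used throughout the package.

Horizon windows are defined in calendar months: ``add_months`` performs
calendar-month addition with day-of-month clamping (Jan 31 + 1 month =
Feb 28/29), which avoids the cumulative drift of fixed 30-day months over a
60-month horizon. Continuous durations (time to cancer, trajectory spans) use
the mean Gregorian month of 30.4375 days.
"""

from __future__ import annotations

import calendar
import datetime as dt

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


def add_months(date: dt.date, months: int) -> dt.date:
    """Calendar-month addition with day clamping."""
    month_index = date.month - 1 + months
    year = date.year + month_index // 12
    month = month_index % 12 + 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def months_between(start: dt.date, end: dt.date) -> float:
    """Signed continuous duration in mean months from `start` to `end`."""
    return (end - start).days / DAYS_PER_MONTH


def years_between(start: dt.date, end: dt.date) -> float:
    """Signed continuous duration in mean years (age arithmetic)."""
    return (end - start).days / DAYS_PER_YEAR
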