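"""Abstract model calendar: a 365-day year starting 1 January, time in seconds."""

from __future__ import annotations

import numpy as np

SECONDS_PER_DAY = 86_400.0
DAYS_PER_YEAR = 365

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])  # day-of-year offsets
SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}
SEASON_ORDER = ["winter", "spring", "summer", "autumn"]


def day_of_year(t_seconds):
    """0-based day of the (wrapped) model year for a time in seconds."""
    day = np.floor_divide(np.asarray(t_seconds), SECONDS_PER_DAY).astype(int)
    return np.mod(day, DAYS_PER_YEAR)


def month_of_time(t_seconds):
    """1-based month number for a model time in seconds (year-wrapped)."""
    doy = day_of_year(t_seconds)
    return np.searchsorted(MONTH_STARTS, doy, side="right").astype(int)


def day_to_seconds(day_1based: float) -> float:
    """Convert a 1-based day-of-year to seconds at that day's midnight."""
    return (float(day_1based) - 1.0) * SECONDS_PER_DAY


def season_of_month(month: int) -> str:
    return SEASON_OF_MONTH[int(month)]
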