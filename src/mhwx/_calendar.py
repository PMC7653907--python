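"""365-day (no-leap) calendar helpers.

The simulator and all synthetic analyses run on a fixed 365-day year, which
removes leap-day bookkeeping from tests.  Real-data inputs with a
``datetime64`` time axis are folded onto the same 365-day climatological year:
in leap years, Feb 29 observations are pooled with Feb 28 (day-of-year 59) and
all later dates have their day-of-year shifted down by one, so Mar 1 is always
day 60.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: day-of-year (1-based) on which each month starts
MONTH_START_DOY = np.concatenate([[1], 1 + np.cumsum(MONTH_LENGTHS)[:-1]])


def doy_to_month(doy):
    """Month (1-12) containing each 1-based day-of-year."""
    doy = np.asarray(doy)
    return np.searchsorted(MONTH_START_DOY, doy, side="right").astype(np.int16)


def make_time_axis(start_year: int, n_years: int) -> dict[str, np.ndarray]:
    """Integer time axis for a no-leap record.

    Returns arrays keyed ``ordinal`` (0-based day since record start),
    ``year``, ``dayofyear`` (1-based) and ``month``.
    """
    n = n_years * DAYS_PER_YEAR
    ordinal = np.arange(n)
    year = start_year + ordinal // DAYS_PER_YEAR
    doy = ordinal % DAYS_PER_YEAR + 1
    return {
        "ordinal": ordinal,
        "year": year.astype(np.int32),
        "dayofyear": doy.astype(np.int16),
        "month": doy_to_month(doy),
    }


def ordinal_to_date_str(ordinal, start_year: int):
    """``YYYY-MM-DD`` string(s) for 0-based ordinal day(s) in a no-leap record."""
    scalar = np.isscalar(ordinal)
    ordinal = np.atleast_1d(np.asarray(ordinal, dtype=np.int64))
    year = start_year + ordinal // DAYS_PER_YEAR
    doy = ordinal % DAYS_PER_YEAR + 1
    month = doy_to_month(doy)
    day = doy - MONTH_START_DOY[month - 1] + 1
    out = np.array([f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(year, month, day)])
    return out[0] if scalar else out


def time_components(time_values) -> tuple[np.ndarray, np.ndarray]:
    """(year, day-of-year on the 365-day climatological calendar).

    Accepts either an integer/float ordinal-free axis carrying no calendar
    (rejected), a ``datetime64`` array, or a pandas ``DatetimeIndex``.
    """
    idx = pd.DatetimeIndex(np.asarray(time_values))
    year = np.asarray(idx.year)
    doy = np.asarray(idx.dayofyear, dtype=np.int64)
    leap = np.asarray(idx.is_leap_year)
    # fold Feb 29 (doy 60 in leap years) onto Feb 28's pooling day
    after_feb28 = leap & (doy >= 60)
    doy = np.where(after_feb28, doy - 1, doy)
    return year.astype(np.int32), doy.astype(np.int16)
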