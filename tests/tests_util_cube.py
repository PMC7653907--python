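"""Tiny helper to wrap 1-D series into single-cell SST cubes for tests."""

import numpy as np
import xarray as xr

from mhwx._calendar import DAYS_PER_YEAR, make_time_axis


def cube_1cell(series, start_year=2000):
    series = np.asarray(series, dtype=float)
    n_years = len(series) // DAYS_PER_YEAR
    t = make_time_axis(start_year, n_years)
    return xr.DataArray(
        series[:, None, None], dims=("time", "lat", "lon"),
        coords={"time": t["ordinal"], "year": ("time", t["year"]),
                "dayofyear": ("time", t["dayofyear"]),
                "month": ("time", t["month"]),
                "lat": [0.0], "lon": [0.0]},
        attrs={"start_year": start_year})
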