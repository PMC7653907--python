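"""Day-of-year SST climatology and the seasonally varying percentile threshold.

For each calendar day *d* and grid cell, every baseline observation whose
day-of-year falls within a centred window around *d* (circular across the
year boundary) is pooled; the climatological mean is the mean of that pool
and the threshold is its 90th percentile.  Both fields are then smoothed
with a centred circular moving average to remove day-to-day sampling noise.
Cells/days where the threshold does not exceed the mean (zero-variance
input) are flagged degenerate rather than producing infinite severities.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from ._calendar import DAYS_PER_YEAR, time_components

__all__ = ["build_climatology", "remove_seasonal_trend", "smooth_doy"]


def _year_doy(sst: xr.DataArray) -> tuple[np.ndarray, np.ndarray]:
    """Per-timestep (year, day-of-year) on the 365-day climatological year."""
    if "year" in sst.coords and "dayofyear" in sst.coords:
        return (sst["year"].values.astype(np.int64),
                sst["dayofyear"].values.astype(np.int64))
    if np.issubdtype(np.asarray(sst["time"].values).dtype, np.datetime64):
        y, d = time_components(sst["time"].values)
        return y.astype(np.int64), d.astype(np.int64)
    raise ValueError(
        "SST cube needs either 'year'/'dayofyear' coordinates or a "
        "datetime64 time axis")


def _stack_by_year(sst: xr.DataArray, years_sel: np.ndarray,
                   year: np.ndarray, doy: np.ndarray) -> np.ndarray:
    """Rearrange baseline data into (year, 365, lat, lon), NaN where absent."""
    ny = len(years_sel)
    spatial = sst.shape[1:]
    out = np.full((ny, DAYS_PER_YEAR) + spatial, np.nan, dtype=np.float64)
    year_index = {y: i for i, y in enumerate(years_sel)}
    in_base = np.isin(year, years_sel)
    iy = np.array([year_index[y] for y in year[in_base]], dtype=np.int64)
    idx = iy * DAYS_PER_YEAR + (doy[in_base] - 1)
    vals = sst.values[in_base].astype(np.float64)
    flat = out.reshape(ny * DAYS_PER_YEAR, *spatial)
    if len(np.unique(idx)) == len(idx):
        flat[idx] = vals
    else:
        # real-calendar leap folding maps Feb 29 onto Feb 28's slot: average
        sums = np.zeros_like(flat)
        cnt = np.zeros_like(flat)
        np.add.at(sums, idx, np.nan_to_num(vals))
        np.add.at(cnt, idx, np.isfinite(vals).astype(np.float64))
        with np.errstate(invalid="ignore"):
            averaged = sums / cnt
        has_data = cnt > 0
        flat[has_data] = averaged[has_data]
    return out


def smooth_doy(field: np.ndarray, width: int) -> np.ndarray:
    """Centred circular moving average along the leading day-of-year axis."""
    if width <= 1:
        return field
    from scipy.ndimage import uniform_filter1d
    return uniform_filter1d(field, size=width, axis=0, mode="wrap")


def build_climatology(sst: xr.DataArray, baseline: tuple[int, int],
                      window: int = 11, smooth: int = 31,
                      percentile: float = 90.0,
                      interpolation: str = "linear") -> xr.Dataset:
    """Build the climatological mean and percentile-threshold fields.

    Parameters
    ----------
    sst
        Daily SST, dims ``(time, lat, lon)``, with ``year``/``dayofyear``
        coordinates or a ``datetime64`` time axis.
    baseline
        Inclusive year range used for the climatology.
    window
        Width (days, odd) of the pooling window around each day-of-year.
    smooth
        Width (days, odd) of the circular moving-average smoother, applied to
        both the mean and the threshold.
    percentile
        Threshold percentile (90 reproduces the standard definition).
    interpolation
        Percentile convention: ``"linear"`` (interpolated order statistics)
        or ``"nearest"`` (nearest rank).  Thresholds differ at small sample
        size, so the choice is stored on the output.

    Returns
    -------
    xarray.Dataset
        ``clim_mean`` and ``pc90`` with dims ``(dayofyear, lat, lon)``, their
        unsmoothed counterparts ``clim_mean_raw``/``pc90_raw``, and a boolean
        ``degenerate`` mask where the threshold fails to exceed the mean.
    """
    if window % 2 == 0 or smooth % 2 == 0 or window < 1 or smooth < 1:
        raise ValueError("window and smooth must be odd positive integers")
    year, doy = _year_doy(sst)
    y0, y1 = int(baseline[0]), int(baseline[1])
    if y1 < y0:
        raise ValueError("baseline range is inverted")
    if y0 < year.min() or y1 > year.max():
        raise ValueError("baseline extends outside the SST record")
    years_sel = np.arange(y0, y1 + 1)
    if len(years_sel) < 1:
        raise ValueError("baseline must contain at least one full year")

    stacked = _stack_by_year(sst, years_sel, year, doy)   # (ny, 365, ...)
    hw = (window - 1) // 2
    spatial = stacked.shape[2:]
    mean_raw = np.empty((DAYS_PER_YEAR,) + spatial)
    pc_raw = np.empty((DAYS_PER_YEAR,) + spatial)
    method = {"linear": "linear", "nearest": "nearest"}[interpolation]
    offsets = np.arange(-hw, hw + 1)
    for d in range(DAYS_PER_YEAR):
        pool = stacked[:, (d + offsets) % DAYS_PER_YEAR]     # (ny, window, ...)
        flat = pool.reshape(-1, *spatial)
        with np.errstate(invalid="ignore"):
            mean_raw[d] = np.nanmean(flat, axis=0)
            pc_raw[d] = np.nanpercentile(flat, percentile, axis=0, method=method)

    mean_s = smooth_doy(mean_raw, smooth)
    pc_s = smooth_doy(pc_raw, smooth)
    degenerate = ~(pc_s > mean_s)    # includes NaN (all-missing) cells

    ds = xr.Dataset(
        {
            "clim_mean": (("dayofyear",) + sst.dims[1:], mean_s),
            "pc90": (("dayofyear",) + sst.dims[1:], pc_s),
            "clim_mean_raw": (("dayofyear",) + sst.dims[1:], mean_raw),
            "pc90_raw": (("dayofyear",) + sst.dims[1:], pc_raw),
            "degenerate": (("dayofyear",) + sst.dims[1:], degenerate),
        },
        coords={"dayofyear": np.arange(1, DAYS_PER_YEAR + 1),
                **{d: sst.coords[d] for d in sst.dims[1:] if d in sst.coords}},
        attrs={
            "baseline_start": y0, "baseline_end": y1,
            "window_days": window, "smooth_days": smooth,
            "percentile": percentile, "percentile_convention": interpolation,
            "units": "degC",
        },
    )
    return ds


def remove_seasonal_trend(sst: xr.DataArray, window: int = 11) -> xr.DataArray:
    """Remove a day-of-year-resolved linear trend from an SST record.

    For every day-of-year (pooled with a centred circular window) and cell,
    an OLS slope of SST against year is fitted and the fitted anomaly about
    the record-mean year is subtracted, so each calendar day is trend-free by
    construction while the seasonal cycle and variability are retained.
    """
    year, doy = _year_doy(sst)
    years_all = np.arange(year.min(), year.max() + 1)
    if len(years_all) < 10:
        raise ValueError("need at least a 10-year record to estimate trends")
    stacked = _stack_by_year(sst, years_all, year, doy)     # (ny, 365, ...)
    ny = len(years_all)
    hw = (window - 1) // 2
    offsets = np.arange(-hw, hw + 1)
    yrs = years_all.astype(float)
    spatial = stacked.shape[2:]
    slope = np.empty((DAYS_PER_YEAR,) + spatial)
    for d in range(DAYS_PER_YEAR):
        pool = stacked[:, (d + offsets) % DAYS_PER_YEAR]     # (ny, window, ...)
        x = np.broadcast_to(yrs[:, None], (ny, len(offsets)))
        x = x.reshape(-1, *([1] * len(spatial)))
        v = pool.reshape(ny * len(offsets), *spatial)
        ok = np.isfinite(v)
        n = ok.sum(axis=0)
        xm = np.where(ok, x, 0.0).sum(axis=0) / np.maximum(n, 1)
        vm = np.where(ok, v, 0.0).sum(axis=0) / np.maximum(n, 1)
        dx = np.where(ok, x - xm, 0.0)
        cov = (dx * np.where(ok, v - vm, 0.0)).sum(axis=0)
        var = (dx ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = cov / var
        slope[d] = np.where((n >= 10) & (var > 0), s, np.nan)

    year_center = yrs.mean()
    adjust = slope[doy - 1] * (year.astype(float) - year_center)[:, None, None]
    out = sst.copy(deep=True)
    out.values = sst.values - adjust
    return out
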