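"""Atmospheric-driver composites around extreme-event peaks.

For each region and driver field, the region-mean daily series is averaged
over a fixed calendar window before (default 6 to 2 weeks prior) and after
(2 to 6 weeks) the event peak.  The anomaly is taken against the mean of the
same calendar window across all available years and normalized by the
across-year standard deviation of that window, making anomalies from
different fields and regions directly comparable.  A window whose absolute
anomaly ranks among the floor(n/10) most extreme years is flagged top
decile; the single most extreme is flagged a record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from ._calendar import DAYS_PER_YEAR

__all__ = ["WindowAnomaly", "window_normalized_anomaly", "driver_composites",
           "region_mean_series", "PRE_WINDOW", "POST_WINDOW",
           "PRE_WINDOW_SHORT", "POST_WINDOW_SHORT"]

#: day offsets (inclusive) relative to the peak; 4-week windows
PRE_WINDOW = (-42, -15)
POST_WINDOW = (15, 42)
#: 3-week variant (6 to 3 weeks prior / 3 to 6 weeks after)
PRE_WINDOW_SHORT = (-42, -22)
POST_WINDOW_SHORT = (22, 42)


@dataclass
class WindowAnomaly:
    norm_anom: float
    top_decile: bool
    record: bool
    n_years: int
    truncated: bool


def window_normalized_anomaly(series: np.ndarray, peak: int,
                              offsets: tuple[int, int] = PRE_WINDOW,
                              min_coverage: float = 0.75) -> WindowAnomaly | None:
    """Normalized calendar-window anomaly of a daily series around a peak.

    ``series`` is the full multi-year daily record (no-leap calendar,
    starting on day-of-year 1); ``peak`` is the 0-based ordinal of the event
    peak.  The same calendar window (anchored at the peak's day-of-year) is
    evaluated in every year with at least ``min_coverage`` of its days in
    record; returns None when the event year's own window is below coverage.
    """
    n = len(series)
    n_years = n // DAYS_PER_YEAR
    peak_doy = peak % DAYS_PER_YEAR
    event_year = peak // DAYS_PER_YEAR
    lo, hi = offsets
    width = hi - lo + 1

    means = np.full(n_years, np.nan)
    truncated = False
    for y in range(n_years):
        center = y * DAYS_PER_YEAR + peak_doy
        a, b = center + lo, center + hi
        aa, bb = max(a, 0), min(b, n - 1)
        if bb < aa:
            continue
        vals = series[aa:bb + 1]
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_coverage * width:
            if y == event_year:
                return None
            continue
        if (a < 0 or b > n - 1) and y == event_year:
            truncated = True
        means[y] = vals.mean()

    ok = np.isfinite(means)
    if ok.sum() < 3 or not np.isfinite(means[event_year]):
        return None
    clim = means[ok].mean()
    std = means[ok].std(ddof=1)
    if std == 0:
        return None
    anoms = means - clim
    norm = anoms[event_year] / std

    order = np.argsort(-np.abs(anoms[ok]), kind="stable")
    years_ok = np.flatnonzero(ok)
    rank = int(np.flatnonzero(years_ok[order] == event_year)[0]) + 1
    k = max(1, int(ok.sum() // 10))
    return WindowAnomaly(norm_anom=float(norm), top_decile=rank <= k,
                         record=rank == 1, n_years=int(ok.sum()),
                         truncated=truncated)


def region_mean_series(field: xr.DataArray, cells: np.ndarray,
                       areas_km2: np.ndarray) -> np.ndarray:
    """Area-weighted region mean of a daily (time, lat, lon) field."""
    ilat, ilon = cells[:, 0], cells[:, 1]
    w = areas_km2[ilat]
    sub = field.values[:, ilat, ilon]
    return (sub * w).sum(axis=1) / w.sum()


def driver_composites(regions: list, fields: xr.Dataset,
                      areas_km2: np.ndarray,
                      pre: tuple[int, int] = PRE_WINDOW,
                      post: tuple[int, int] = POST_WINDOW,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Composite table, sign-agreement summary and wind–latent correlation.

    ``regions`` are characterized :class:`~mhwx.extremes.ExtremeRegion`
    objects with a ``peak_t``; regions without one are excluded.  Returns
    (per-region table, per-field/phase sign-agreement percentages, and the
    cross-region Pearson correlation between pre-peak wind-speed and latent
    heat flux anomalies with a two-sided p-value).
    """
    rows = []
    for region in regions:
        if region.peak_t is None:
            continue
        for name in fields.data_vars:
            series = region_mean_series(fields[name], region.cells, areas_km2)
            for phase, offs in (("pre", pre), ("post", post)):
                wa = window_normalized_anomaly(series, region.peak_t, offs)
                if wa is None:
                    continue
                rows.append({"region_id": region.region_id, "field": name,
                             "phase": phase, "norm_anom": wa.norm_anom,
                             "top_decile": wa.top_decile, "record": wa.record,
                             "truncated": wa.truncated,
                             "lat_center": region.lat_center})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, pd.DataFrame(), {}

    agree = (table.groupby(["field", "phase"])["norm_anom"]
             .agg(pct_positive=lambda x: 100.0 * (x > 0).mean(),
                  n="count").reset_index())

    corr: dict = {}
    pre_tab = table[table.phase == "pre"].pivot_table(
        index="region_id", columns="field", values="norm_anom")
    if {"wind_speed", "latent"} <= set(pre_tab.columns):
        sub = pre_tab[["wind_speed", "latent"]].dropna()
        if len(sub) >= 3:
            r, p = stats.pearsonr(sub["wind_speed"], sub["latent"])
            corr = {"r_wind_latent": float(r), "p_value": float(p),
                    "n_regions": len(sub)}
    return table, agree, corr
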