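"""Niño3.4 index, ENSO phase classification and SSTA regression maps.

The index is the area-weighted monthly SST anomaly over the equatorial
Pacific box 5°S–5°N, 170°W–120°W, standardized by its base-period standard
deviation.  |index| > 1 marks moderate and |index| > 2 strong events, the
sign separating El Niño from La Niña.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .spatial import cell_areas

__all__ = ["nino34_series", "record_fraction_by_phase", "regress_index_map",
           "NINO34_BOX"]

#: (lat_min, lat_max, lon_min, lon_max), °E
NINO34_BOX = (-5.0, 5.0, 190.0, 240.0)

PHASES = ["la_nina_strong", "la_nina_moderate", "neutral",
          "el_nino_moderate", "el_nino_strong"]


def _classify(idx: np.ndarray) -> np.ndarray:
    phase = np.full(idx.shape, "neutral", dtype=object)
    phase[idx > 1] = "el_nino_moderate"
    phase[idx > 2] = "el_nino_strong"
    phase[idx < -1] = "la_nina_moderate"
    phase[idx < -2] = "la_nina_strong"
    return phase


def nino34_series(monthly_ssta: xr.DataArray,
                  box: tuple[float, float, float, float] = NINO34_BOX,
                  base_years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Standardized Niño3.4-like index with per-month phase labels.

    ``monthly_ssta`` must carry ``myear``/``mmonth`` coordinates on its
    leading time dimension.  Standardization uses the base-period std
    (defaulting to the full record).
    """
    lat = monthly_ssta["lat"].values
    lon = monthly_ssta["lon"].values
    in_box = ((lat[:, None] >= box[0]) & (lat[:, None] <= box[1])
              & (lon[None, :] >= box[2]) & (lon[None, :] <= box[3]))
    if not in_box.any():
        raise ValueError("index box does not intersect the grid")
    lat_step = float(np.diff(lat).mean()) if len(lat) > 1 else 1.0
    lon_step = float(np.diff(lon).mean()) if len(lon) > 1 else 1.0
    w2d = np.broadcast_to(
        cell_areas(lat, lat_step, lon_step)[:, None], in_box.shape)
    w = np.where(in_box, w2d, 0.0)
    vals = monthly_ssta.values
    raw = np.nansum(vals * w, axis=(1, 2)) / w.sum()

    years = monthly_ssta["myear"].values
    months = monthly_ssta["mmonth"].values
    if base_years is None:
        base_years = (int(years.min()), int(years.max()))
    in_base = (years >= base_years[0]) & (years <= base_years[1])
    centered = raw - raw[in_base].mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = centered / centered[in_base].std(ddof=1)
    return pd.DataFrame({"year": years, "month": months, "index": idx,
                         "phase": _classify(idx)})


def record_fraction_by_phase(records: xr.Dataset, enso: pd.DataFrame,
                             areas_km2: np.ndarray,
                             metric: str = "t_max_sev",
                             start_year: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Ocean-area fractions attaining their record per month and per phase.

    The record day of each cell (``t_max_sev`` record-severity day,
    ``t_max_int`` record-intensity day, or ``t_longest_center`` central day
    of the longest event) is attributed to the month containing it; monthly
    fractions are area-weighted and the cumulative fraction per ENSO phase
    sums the months in that phase.
    """
    from ._calendar import DAYS_PER_YEAR, doy_to_month

    if start_year is None:
        start_year = int(records.attrs.get("start_year", int(enso["year"].min())))
    t = records[metric].values
    ok = np.isfinite(t)
    area2d = np.broadcast_to(areas_km2[:, None], t.shape)
    total = area2d[ok].sum()

    t_int = np.nan_to_num(t).astype(np.int64)
    year = start_year + t_int // DAYS_PER_YEAR
    month = doy_to_month(t_int % DAYS_PER_YEAR + 1)

    key = enso.set_index(["year", "month"])
    rows = []
    for (y, m), g in key.groupby(level=[0, 1]):
        sel = ok & (year == y) & (month == m)
        rows.append({"year": y, "month": m,
                     "index": g["index"].iloc[0], "phase": g["phase"].iloc[0],
                     "record_area_fraction": area2d[sel].sum() / total})
    monthly = pd.DataFrame(rows).sort_values(["year", "month"]).reset_index(drop=True)
    by_phase = (monthly.groupby("phase")["record_area_fraction"].sum()
                .reindex(PHASES, fill_value=0.0).to_dict())
    return monthly, by_phase


def regress_index_map(enso: pd.DataFrame, monthly_ssta: xr.DataArray,
                      min_months: int = 24) -> xr.DataArray:
    """Per-cell OLS slope of monthly SSTA on the standardized index.

    Units are °C per index standard deviation; cells with fewer than
    ``min_months`` overlapping finite months are masked.
    """
    years = monthly_ssta["myear"].values
    months = monthly_ssta["mmonth"].values
    lut = {(y, m): v for y, m, v in zip(enso["year"], enso["month"], enso["index"])}
    idx = np.array([lut.get((y, m), np.nan) for y, m in zip(years, months)])
    v = monthly_ssta.values
    ok = np.isfinite(idx)[:, None, None] & np.isfinite(v)
    x = np.where(ok, idx[:, None, None], 0.0)
    y = np.where(ok, v, 0.0)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = x.sum(axis=0) / n
        ym = y.sum(axis=0) / n
        dx = np.where(ok, x - xm, 0.0)
        cov = (dx * np.where(ok, y - ym, 0.0)).sum(axis=0)
        var = (dx ** 2).sum(axis=0)
        slope = np.where((n >= min_months) & (var > 0), cov / var, np.nan)
    return xr.DataArray(slope, dims=("lat", "lon"),
                        coords={"lat": monthly_ssta["lat"],
                                "lon": monthly_ssta["lon"]},
                        name="enso_regression",
                        attrs={"units": "degC per index s.d."})
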