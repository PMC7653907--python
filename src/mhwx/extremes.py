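"""Record maps, record seasonality and "most extreme extreme" regions.

The most extreme events are located where a cell's most severe recorded day
falls inside the span of that cell's largest-cumulative-intensity event —
the intersection of "most severe" with "most prolonged/accumulated".
Coherent regions of such cells are delineated either by user-supplied
polygons (faithful to hand-drawn analyses) or by a deterministic fallback
that connects candidate cells whose record dates agree within a window.
Each region is then characterized by extent/intensity time series, a core
date range, and the associated summary metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import DAYS_PER_YEAR, doy_to_month, ordinal_to_date_str
from .spatial import label_contiguous, _UnionFind

__all__ = ["record_maps", "record_seasonality", "identify_extreme_regions",
           "characterize_region", "regions_table", "regions_to_geojson",
           "ExtremeRegion"]

#: months of local summer / winter per hemisphere
SEASONS = {"DJF": (12, 1, 2), "MAM": (3, 4, 5), "JJA": (6, 7, 8), "SON": (9, 10, 11)}


def record_maps(rollup: pd.DataFrame, lat: np.ndarray, lon: np.ndarray,
                start_year: int = 0) -> xr.Dataset:
    """Per-cell record metrics as gridded maps (NaN where a cell has no events).

    Input is the per-cell rollup from
    :func:`mhwx.detection.event_metrics_rollup`.
    """
    shape = (len(lat), len(lon))
    fields = {
        "max_cat": np.full(shape, np.nan),
        "max_int_C": np.full(shape, np.nan),
        "t_max_int": np.full(shape, np.nan),
        "max_sev": np.full(shape, np.nan),
        "t_max_sev": np.full(shape, np.nan),
        "longest_d": np.full(shape, np.nan),
        "longest_start": np.full(shape, np.nan),
        "longest_end": np.full(shape, np.nan),
        "t_longest_center": np.full(shape, np.nan),
        "max_cum_Cd": np.full(shape, np.nan),
        "max_cum_start": np.full(shape, np.nan),
        "max_cum_end": np.full(shape, np.nan),
    }
    if not rollup.empty:
        i = rollup["ilat"].to_numpy()
        j = rollup["ilon"].to_numpy()
        fields["max_cat"][i, j] = rollup["max_cat"]
        fields["max_int_C"][i, j] = rollup["max_int_C"]
        fields["t_max_int"][i, j] = rollup["t_max_int"]
        fields["max_sev"][i, j] = rollup["max_sev"]
        fields["t_max_sev"][i, j] = rollup["t_max_sev"]
        fields["longest_d"][i, j] = rollup["longest_d"]
        fields["longest_start"][i, j] = rollup["longest_start"]
        fields["longest_end"][i, j] = rollup["longest_end"]
        fields["t_longest_center"][i, j] = (
            (rollup["longest_start"] + rollup["longest_end"]) // 2)
        fields["max_cum_Cd"][i, j] = rollup["max_cum_Cd"]
        fields["max_cum_start"][i, j] = rollup["max_cum_start"]
        fields["max_cum_end"][i, j] = rollup["max_cum_end"]
    ds = xr.Dataset(
        {k: (("lat", "lon"), v) for k, v in fields.items()},
        coords={"lat": lat, "lon": lon},
        attrs={"start_year": start_year})
    return ds


def _month_of(t_ordinal: np.ndarray) -> np.ndarray:
    doy = (np.asarray(t_ordinal, dtype=np.int64) % DAYS_PER_YEAR) + 1
    return doy_to_month(doy)


def record_seasonality(records: xr.Dataset, areas_km2: np.ndarray,
                       metric: str = "t_max_int",
                       hemisphere_edge: float = 5.0,
                       exclude_months: np.ndarray | None = None,
                       ) -> pd.DataFrame:
    """Area fraction of each hemisphere whose record falls in each month.

    ``metric`` names the record-date field (``t_max_int`` for the most
    intense day, ``t_max_sev`` for the most severe).  ``exclude_months`` is
    an optional boolean series over record months (e.g. El Niño months);
    cells whose record month is flagged are dropped before normalizing, so
    fractions always sum to 1 within each hemisphere.

    Returns a tidy frame with hemisphere, month, season, and area fraction.
    """
    lat = records["lat"].values
    t = records[metric].values
    area2d = np.broadcast_to(areas_km2[:, None], t.shape)
    month = np.where(np.isfinite(t), _month_of(np.nan_to_num(t)), 0)

    rows = []
    for hemi, sel_lat in (("NH", lat > hemisphere_edge),
                          ("SH", lat < -hemisphere_edge)):
        sel = sel_lat[:, None] & (month > 0)
        if exclude_months is not None:
            # month index since record start, for phase-based exclusion
            mo_idx = (np.nan_to_num(t).astype(np.int64) // DAYS_PER_YEAR) * 12 \
                + month - 1
            sel &= ~np.where(sel, exclude_months[np.clip(mo_idx, 0, len(exclude_months) - 1)], False)
        total = area2d[sel].sum()
        for m in range(1, 13):
            a = area2d[sel & (month == m)].sum()
            season = next(s for s, ms in SEASONS.items() if m in ms)
            rows.append({"hemisphere": hemi, "month": m, "season": season,
                         "area_fraction": a / total if total > 0 else np.nan})
    return pd.DataFrame(rows)


@dataclass
class ExtremeRegion:
    """One extreme-event region with its characterization."""

    region_id: int
    cells: np.ndarray                      # (n, 2) (ilat, ilon)
    core_start: int | None = None
    core_end: int | None = None
    peak_t: int | None = None
    lat_center: float = np.nan
    # summary metrics (within the core period)
    max_area_s1_Mkm2: float = np.nan
    t_max_area_s1: int | None = None
    max_area_s2_Mkm2: float = np.nan
    t_max_area_s2: int | None = None
    max_int_s1_C_Mkm2: float = np.nan
    t_max_int_s1: int | None = None
    max_int_s2_C_Mkm2: float = np.nan
    t_max_int_s2: int | None = None
    duration_median_d: float = np.nan
    duration_iqr_d: tuple[float, float] = (np.nan, np.nan)
    timeseries: pd.DataFrame | None = dc_field(default=None, repr=False)


def identify_extreme_regions(records: xr.Dataset,
                             polygons: list | None = None,
                             date_window_d: int = 90,
                             min_cells: int = 4,
                             connectivity: int = 8,
                             wrap_longitude: bool = True,
                             ) -> tuple[np.ndarray, list[ExtremeRegion]]:
    """Candidate mask and region shells for the most extreme events.

    A cell is a candidate when its most severe recorded day lies within the
    span of its largest-cumulative-intensity event.  Regions are either the
    supplied shapely polygons intersected with the candidate mask, or — by
    default — connected components of candidate cells whose most-severe
    dates agree within ``date_window_d`` days, keeping components of at
    least ``min_cells`` cells.  The fallback is fully deterministic.
    """
    t_sev = records["t_max_sev"].values
    c_start = records["max_cum_start"].values
    c_end = records["max_cum_end"].values
    with np.errstate(invalid="ignore"):
        candidate = (t_sev >= c_start) & (t_sev <= c_end)
    candidate &= np.isfinite(t_sev)

    lat = records["lat"].values
    lon = records["lon"].values
    regions: list[ExtremeRegion] = []

    if polygons is not None:
        from shapely.geometry import Point
        for rid, poly in enumerate(polygons):
            sel = np.zeros_like(candidate)
            for i in range(len(lat)):
                for j in range(len(lon)):
                    if candidate[i, j] and poly.contains(Point(lon[j], lat[i])):
                        sel[i, j] = True
            cells = np.argwhere(sel)
            if len(cells):
                regions.append(_shell(rid, cells, lat))
        return candidate, regions

    nlat, nlon = candidate.shape
    idx = -np.ones((nlat, nlon), dtype=np.int64)
    cand_cells = np.argwhere(candidate)
    for k, (i, j) in enumerate(cand_cells):
        idx[i, j] = k
    uf = _UnionFind(len(cand_cells))
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1)]
    else:
        neigh = [(-1, 0), (0, -1)]
    for k, (i, j) in enumerate(cand_cells):
        for di, dj in neigh:
            ii = i + di
            jj = (j + dj) % nlon if wrap_longitude else j + dj
            if ii < 0 or ii >= nlat or jj < 0 or jj >= nlon:
                continue
            kk = idx[ii, jj]
            if kk >= 0 and abs(t_sev[i, j] - t_sev[ii, jj]) <= date_window_d:
                uf.union(k, kk)
    roots = np.array([uf.find(k) for k in range(len(cand_cells))])
    rid = 0
    for root in np.unique(roots):
        cells = cand_cells[roots == root]
        if len(cells) >= min_cells:
            regions.append(_shell(rid, cells, lat))
            rid += 1
    return candidate, regions


def _shell(rid: int, cells: np.ndarray, lat: np.ndarray) -> ExtremeRegion:
    return ExtremeRegion(region_id=rid, cells=cells,
                         lat_center=float(lat[cells[:, 0]].mean()))


def characterize_region(region: ExtremeRegion, sev: xr.DataArray,
                        ssta: xr.DataArray, areas_km2: np.ndarray,
                        records: xr.Dataset, rollup: pd.DataFrame,
                        f_min: float = 0.3, r_min: float = 0.5,
                        category_level: float = 1.0,
                        connectivity: int = 8,
                        wrap_longitude: bool = True,
                        event_mask: np.ndarray | None = None) -> ExtremeRegion:
    """Fill a region shell with its time series, core period and metrics.

    Four daily region series are computed: (i) the fraction of region area
    above ``category_level`` severity, (ii) the largest contiguous event
    area (at S > 1 and S > 2) intersecting the region, (iii) that event's
    area-integrated SSTA, and (iv) the count of member cells experiencing
    their record-severity day.  The core period is the longest run of days
    where (i) exceeds ``f_min`` and the S > 1 contiguous area exceeds
    ``r_min`` of its own maximum; summary maxima are then taken within the
    core, and the member-cell duration spread comes from each cell's
    largest-cumulative-intensity event.

    ``event_mask`` (from :func:`mhwx.detection.event_state_mask`) restricts
    heatwave state to detected events, which keeps sub-5-day threshold
    exceedances out of the fraction and contiguous-extent series.
    """
    cells = region.cells
    ilat, ilon = cells[:, 0], cells[:, 1]
    nlat, nlon = sev.shape[1:]
    member = np.zeros((nlat, nlon), dtype=bool)
    member[ilat, ilon] = True
    w = areas_km2[ilat]
    region_area = w.sum()
    nt = sev.sizes["time"]

    s_all = sev.values
    a_all = ssta.values
    t_sev_rec = records["t_max_sev"].values

    frac = np.zeros(nt)
    area_s1 = np.zeros(nt)
    int_s1 = np.zeros(nt)
    area_s2 = np.zeros(nt)
    int_s2 = np.zeros(nt)
    n_record = np.zeros(nt, dtype=np.int64)
    mean_sev = np.full(nt, np.nan)

    rec_days = t_sev_rec[ilat, ilon]
    ok = np.isfinite(rec_days)
    vals, counts = np.unique(rec_days[ok].astype(np.int64), return_counts=True)
    n_record[vals[vals < nt]] = counts[vals < nt]

    for t in range(nt):
        s = s_all[t]
        with np.errstate(invalid="ignore"):
            above = s > category_level
        if event_mask is not None:
            above &= event_mask[t]
        frac[t] = areas_km2[ilat[above[ilat, ilon]]].sum() / region_area
        sv = s[ilat, ilon]
        if np.isfinite(sv).any():
            mean_sev[t] = np.nansum(sv * w) / region_area
        for thresh, a_arr, i_arr in ((1.0, area_s1, int_s1), (2.0, area_s2, int_s2)):
            with np.errstate(invalid="ignore"):
                mask = s > thresh
            if event_mask is not None:
                mask &= event_mask[t]
            comps = label_contiguous(mask, areas_km2, a_all[t],
                                     connectivity, wrap_longitude, t=t)
            best = None
            for c in comps:
                if member[c.cells[:, 0], c.cells[:, 1]].any():
                    if best is None or c.area_Mkm2 > best.area_Mkm2:
                        best = c
            if best is not None:
                a_arr[t] = best.area_Mkm2
                i_arr[t] = best.int_ssta_C_Mkm2

    ts = pd.DataFrame({"t": np.arange(nt), "frac_above": frac,
                       "area_s1_Mkm2": area_s1, "int_s1_C_Mkm2": int_s1,
                       "area_s2_Mkm2": area_s2, "int_s2_C_Mkm2": int_s2,
                       "n_record_cells": n_record, "mean_severity": mean_sev})
    region.timeseries = ts

    amax = area_s1.max()
    if amax <= 0 or not (frac > f_min).any():
        return region
    good = (frac > f_min) & (area_s1 > r_min * amax)
    s0, e0 = _longest_run(good)
    region.core_start, region.core_end = s0, e0
    core = slice(s0, e0 + 1)
    region.peak_t = int(s0 + np.nanargmax(mean_sev[core]))

    def _core_max(arr):
        k = int(np.argmax(arr[core]))
        return float(arr[core][k]), int(s0 + k)

    region.max_area_s1_Mkm2, region.t_max_area_s1 = _core_max(area_s1)
    region.max_area_s2_Mkm2, region.t_max_area_s2 = _core_max(area_s2)
    region.max_int_s1_C_Mkm2, region.t_max_int_s1 = _core_max(int_s1)
    region.max_int_s2_C_Mkm2, region.t_max_int_s2 = _core_max(int_s2)

    if not rollup.empty:
        sub = rollup.merge(pd.DataFrame({"ilat": ilat, "ilon": ilon}),
                           on=["ilat", "ilon"])
        if len(sub):
            durs = (sub["max_cum_end"] - sub["max_cum_start"] + 1).to_numpy(float)
            region.duration_median_d = float(np.median(durs))
            region.duration_iqr_d = (float(np.percentile(durs, 25)),
                                     float(np.percentile(durs, 75)))
    return region


def _longest_run(good: np.ndarray) -> tuple[int, int]:
    padded = np.diff(np.concatenate(([0], good.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    k = int(np.argmax(ends - starts))
    return int(starts[k]), int(ends[k])


def regions_table(regions: list[ExtremeRegion], start_year: int = 0) -> pd.DataFrame:
    """Summary table (one row per region) mirroring the seven-metric layout."""
    rows = []
    for r in regions:
        rows.append({
            "region_id": r.region_id,
            "n_cells": len(r.cells),
            "lat_center": r.lat_center,
            "max_int_s2_C_Mkm2": r.max_int_s2_C_Mkm2,
            "date_max_int_s2": _d(r.t_max_int_s2, start_year),
            "max_int_s1_C_Mkm2": r.max_int_s1_C_Mkm2,
            "date_max_int_s1": _d(r.t_max_int_s1, start_year),
            "max_area_s2_Mkm2": r.max_area_s2_Mkm2,
            "date_max_area_s2": _d(r.t_max_area_s2, start_year),
            "max_area_s1_Mkm2": r.max_area_s1_Mkm2,
            "date_max_area_s1": _d(r.t_max_area_s1, start_year),
            "duration_iqr_lo_d": r.duration_iqr_d[0],
            "duration_iqr_hi_d": r.duration_iqr_d[1],
            "duration_median_d": r.duration_median_d,
            "core_start": _d(r.core_start, start_year),
            "core_end": _d(r.core_end, start_year),
        })
    return pd.DataFrame(rows)


def _d(t, start_year):
    return ordinal_to_date_str(int(t), start_year) if t is not None else None


def regions_to_geojson(regions: list[ExtremeRegion], lat: np.ndarray,
                       lon: np.ndarray, lat_step: float, lon_step: float,
                       start_year: int = 0) -> dict:
    """GeoJSON FeatureCollection of region outlines with core dates.

    Each region polygon is the union of its member cells' bounding boxes;
    properties carry the id and the core start/end dates.
    """
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    for r in regions:
        cells = [box(lon[j] - lon_step / 2, lat[i] - lat_step / 2,
                     lon[j] + lon_step / 2, lat[i] + lat_step / 2)
                 for i, j in r.cells]
        geom = unary_union(cells)
        features.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {
                "id": int(r.region_id),
                "core_start": _d(r.core_start, start_year),
                "core_end": _d(r.core_end, start_year),
            },
        })
    return {"type": "FeatureCollection", "features": features}
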