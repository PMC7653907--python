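"""Per-cell marine heatwave detection, severity and event metrics.

An event is a maximal run of at least ``min_duration`` consecutive days with
SST strictly above the seasonally varying threshold; two qualifying runs
separated by no more than ``max_gap`` sub-threshold days are merged into a
single event whose duration includes the gap days.  All intensity metrics
are daily SST anomalies relative to the smoothed climatological mean.

The dimensionless severity index rescales the anomaly by the local
threshold exceedance margin,

    S = (SST - clim) / (pc90 - clim),

so S = 1 exactly at the threshold everywhere, and categories are banded as
moderate (1 < S <= 2), strong (2 < S <= 3), severe (3 < S <= 4) and
extreme (S > 4).  Severity is scale-free: it is invariant under any affine
transformation applied jointly to SST, climatology and threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import ordinal_to_date_str

__all__ = [
    "severity",
    "category_from_severity",
    "detect_events",
    "detect_events_grid",
    "event_metrics_rollup",
    "event_state_mask",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "ilat", "ilon", "lat", "lon", "start", "end", "start_date", "end_date",
    "duration_d", "max_int_C", "t_max_int", "date_max_int", "cum_int_Cd",
    "max_sev", "t_max_sev", "max_cat",
]


def category_from_severity(s):
    """Ordinal category 0-4 from the severity index (0 = below moderate)."""
    s = np.asarray(s, dtype=float)
    cat = np.ceil(s - 1e-9) - 1
    cat = np.clip(cat, 0, 4)
    cat = np.where(s <= 1.0, 0, cat)
    return np.where(np.isfinite(s), cat, 0).astype(np.int8)


def severity(sst: xr.DataArray, clim: xr.Dataset,
             events: pd.DataFrame | None = None) -> xr.Dataset:
    """Pointwise severity index and category fields.

    Degenerate cells (threshold not above the mean) are masked to NaN and
    counted in a log message rather than producing infinities.  When the
    event table is supplied, the category field is zeroed outside detected
    events, so category > 0 holds exactly where a heatwave is in progress
    and S > 1.
    """
    doy = sst["dayofyear"].values.astype(np.int64) - 1
    cm = clim["clim_mean"].values[doy]
    pc = clim["pc90"].values[doy]
    degen = clim["degenerate"].values[doy]
    denom = pc - cm
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (sst.values - cm) / denom
    bad = degen | ~np.isfinite(s)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("severity: masked %d degenerate cell-days", n_bad)
    s = np.where(bad, np.nan, s)
    sev = xr.DataArray(s.astype(np.float32), dims=sst.dims, coords=sst.coords,
                       name="severity")
    cat_vals = category_from_severity(s)
    if events is not None:
        in_event = event_state_mask(events, *s.shape)
        cat_vals = np.where(in_event, cat_vals, 0).astype(np.int8)
    cat = xr.DataArray(cat_vals, dims=sst.dims,
                       coords=sst.coords, name="category")
    return xr.Dataset({"severity": sev, "category": cat})


def event_state_mask(events: pd.DataFrame, n_time: int,
                     nlat: int, nlon: int) -> np.ndarray:
    """Boolean (time, lat, lon) mask of days each cell is inside an event.

    Heatwave *state* — and hence category and contiguous extent — exists
    only while a detected event is in progress; brief threshold exceedances
    that never qualify as events are excluded by this mask.
    """
    m = np.zeros((n_time, nlat, nlon), dtype=bool)
    for start, end, i, j in zip(events["start"], events["end"],
                                events["ilat"], events["ilon"]):
        m[start:end + 1, i, j] = True
    return m


def _runs(above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end indices (inclusive) of maximal True runs."""
    padded = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return starts, ends


def detect_events(sst: np.ndarray, doy: np.ndarray,
                  clim_mean: np.ndarray, pc90: np.ndarray,
                  min_duration: int = 5, max_gap: int = 1) -> list[dict]:
    """Detect events in one cell's daily series.

    Parameters
    ----------
    sst, doy
        Daily SST values and 1-based day-of-year per timestep.  Missing
        (NaN) days are treated as below threshold and break runs.
    clim_mean, pc90
        Length-365 climatology and threshold for this cell.
    min_duration
        Minimum run length, days.
    max_gap
        Maximum number of below-threshold days bridged between two
        qualifying runs (1 reproduces the "below threshold for < 2 days"
        rule).

    Returns a list of dicts with span and intensity/severity metrics.
    """
    sst = np.asarray(sst, dtype=float)
    d = np.asarray(doy, dtype=np.int64) - 1
    cm = clim_mean[d]
    pc = pc90[d]
    with np.errstate(invalid="ignore"):
        above = sst > pc
    above &= np.isfinite(sst)
    starts, ends = _runs(above)
    keep = (ends - starts + 1) >= min_duration
    starts, ends = starts[keep], ends[keep]
    if len(starts) == 0:
        return []

    merged = [[int(starts[0]), int(ends[0])]]
    for s0, e0 in zip(starts[1:], ends[1:]):
        if s0 - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = int(e0)
        else:
            merged.append([int(s0), int(e0)])

    ssta = sst - cm
    denom = pc - cm
    with np.errstate(invalid="ignore", divide="ignore"):
        sev = ssta / denom
    events = []
    for s0, e0 in merged:
        span = slice(s0, e0 + 1)
        a = ssta[span]
        sv = sev[span]
        imax = int(np.nanargmax(a))
        smax = int(np.nanargmax(sv))
        events.append({
            "start": s0, "end": e0, "duration_d": e0 - s0 + 1,
            "max_int_C": float(a[imax]), "t_max_int": s0 + imax,
            "cum_int_Cd": float(np.nansum(a)),
            "max_sev": float(sv[smax]), "t_max_sev": s0 + smax,
            "max_cat": int(category_from_severity(sv[smax])),
        })
    return events


def detect_events_grid(sst: xr.DataArray, clim: xr.Dataset,
                       min_duration: int = 5, max_gap: int = 1) -> pd.DataFrame:
    """Run :func:`detect_events` over every grid cell; one row per event."""
    doy = sst["dayofyear"].values.astype(np.int64)
    start_year = int(sst.attrs.get("start_year", 0))
    lat = sst["lat"].values
    lon = sst["lon"].values
    cm_all = clim["clim_mean"].values
    pc_all = clim["pc90"].values
    data = sst.values
    rows = []
    for i in range(len(lat)):
        for j in range(len(lon)):
            for ev in detect_events(data[:, i, j], doy, cm_all[:, i, j],
                                    pc_all[:, i, j], min_duration, max_gap):
                ev.update(ilat=i, ilon=j, lat=lat[i], lon=lon[j])
                rows.append(ev)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    df["start_date"] = ordinal_to_date_str(df["start"].values, start_year)
    df["end_date"] = ordinal_to_date_str(df["end"].values, start_year)
    df["date_max_int"] = ordinal_to_date_str(df["t_max_int"].values, start_year)
    return df[EVENT_COLUMNS]


def event_metrics_rollup(events: pd.DataFrame) -> pd.DataFrame:
    """Per-cell record metrics: longest, most cumulative, most intense, most
    severe event.  Ties are broken to the earliest event start."""
    if events.empty:
        return pd.DataFrame(columns=[
            "ilat", "ilon", "lat", "lon", "n_events",
            "longest_d", "longest_start", "longest_end",
            "max_cum_Cd", "max_cum_start", "max_cum_end",
            "max_int_C", "t_max_int", "max_sev", "t_max_sev", "max_cat"])
    ev = events.sort_values(["ilat", "ilon", "start"], kind="stable")
    rows = []
    for (i, j), g in ev.groupby(["ilat", "ilon"], sort=True):
        def best(col):
            # stable sort: first occurrence of the max is the earliest event
            return g.loc[g[col].idxmax()]

        ldur = best("duration_d")
        lcum = best("cum_int_Cd")
        lint = best("max_int_C")
        lsev = best("max_sev")
        rows.append({
            "ilat": i, "ilon": j,
            "lat": g["lat"].iloc[0], "lon": g["lon"].iloc[0],
            "n_events": len(g),
            "longest_d": int(ldur.duration_d),
            "longest_start": int(ldur.start), "longest_end": int(ldur.end),
            "max_cum_Cd": float(lcum.cum_int_Cd),
            "max_cum_start": int(lcum.start), "max_cum_end": int(lcum.end),
            "max_int_C": float(lint.max_int_C), "t_max_int": int(lint.t_max_int),
            "max_sev": float(lsev.max_sev), "t_max_sev": int(lsev.t_max_sev),
            "max_cat": int(g["max_cat"].max()),
        })
    return pd.DataFrame(rows)
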