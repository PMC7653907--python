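"""Synthetic gridded SST, atmosphere and chlorophyll with known ground truth.

The generator emulates the statistical backbone of a satellite-era daily SST
record: a latitude-dependent seasonal cycle with opposed hemispheric phase,
AR(1) daily anomalies whose innovation variance is seasonally modulated
(a proxy for shallow summer mixed layers), an optional linear warming trend,
and an ENSO-like index imprinted through a spatial loading pattern.
Atmospheric driver fields and 8-day chlorophyll composites covary linearly
with the local SST anomaly, so that driver composites and chlorophyll
response statistics computed downstream have a known expected sign.

Heatwave events with known footprint, timing and amplitude can be implanted
on top of the stochastic background (:func:`implant_events`), giving every
downstream detection and characterization stage a truth table to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from ._calendar import DAYS_PER_YEAR, make_time_axis, ordinal_to_date_str

__all__ = [
    "SynthConfig",
    "ImplantSpec",
    "SynthFields",
    "generate_fields",
    "implant_events",
    "trend_duration_experiment",
]

_BURN_DAYS = 400

#: linear coupling of each daily driver field to the local SST anomaly.
#: Flux sign convention is downward-positive, so a positive latent coupling
#: means reduced evaporative heat loss during warm anomalies.
DEFAULT_COUPLINGS = {
    "slp": 1.5,          # hPa per °C   — high pressure over warm anomalies
    "wind_speed": -1.2,  # m s-1 per °C — suppressed winds over warm anomalies
    "u10": -0.8,         # m s-1 per °C
    "swdown": 10.0,      # W m-2 per °C
    "lwdown": 4.0,       # W m-2 per °C
    "latent": 8.0,       # W m-2 per °C
    "sensible": 3.0,     # W m-2 per °C
}

_ATMOS_NOISE_STD = {
    "slp": 4.0, "wind_speed": 2.0, "u10": 2.5, "swdown": 15.0,
    "lwdown": 8.0, "latent": 20.0, "sensible": 8.0,
}
_ATMOS_CLIM = {
    "slp": 1013.0, "wind_speed": 7.0, "u10": 3.0, "swdown": 180.0,
    "lwdown": 340.0, "latent": -100.0, "sensible": -15.0,
}
_ATMOS_UNITS = {
    "slp": "hPa", "wind_speed": "m s-1", "u10": "m s-1", "swdown": "W m-2",
    "lwdown": "W m-2", "latent": "W m-2", "sensible": "W m-2",
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic record.

    Defaults describe a 36-year (1982–2017 analogue) no-leap record on a
    coarse global grid, with mid-latitude-like anomaly statistics: AR(1)
    persistence 0.85 and stationary anomaly std 0.7 °C, a summer:winter
    noise-std ratio of 1.5 standing in for seasonal mixed-layer shoaling, a
    0.2 °C/decade warming trend, and a unit-variance ENSO-like index loaded
    onto an equatorial Gaussian pattern.
    """

    lat_min: float = -65.0
    lat_max: float = 65.0
    lat_step: float = 10.0
    lon_min: float = 0.0
    lon_max: float = 360.0
    lon_step: float = 10.0
    start_year: int = 1982
    n_years: int = 36
    seasonal_amp_max: float = 4.0       # °C, amplitude of the annual cycle at the poleward edge
    sst_peak_doy_nh: float = 226.0      # mid-August climatological SST maximum
    phase_offset_days: float = 182.5    # hemispheric phase opposition
    ar1_phi: float = 0.85               # day-to-day anomaly persistence
    noise_std: float = 0.7              # °C, stationary std of the AR(1) anomaly
    modulation_ratio: float = 1.5       # summer:winter anomaly-std ratio (mixed-layer proxy)
    noise_peak_doy_nh: float = 197.0    # mid-July: variance peaks before the SST maximum
    trend_C_per_decade: float = 0.2
    enso_rho: float = 0.9               # month-to-month index autocorrelation
    enso_amp: float = 1.0               # index std (dimensionless)
    enso_loading_amp: float = 1.0       # °C per index unit at the pattern centre
    enso_loading_center: tuple[float, float] = (0.0, 210.0)   # (lat, lon °E)
    enso_loading_scale: tuple[float, float] = (12.0, 50.0)    # (lat, lon) e-folding, degrees
    chl_coupling: float = 0.2           # log10(mg m-3) per °C at the asymptote
    chl_switch_lat: float = 40.0        # |lat| where the chlorophyll response changes sign
    chl_noise_std: float = 0.12         # log10 units per 8-day composite
    couplings: dict = field(default_factory=lambda: dict(DEFAULT_COUPLINGS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.noise_std <= 0:
            raise ValueError("noise std must be positive")
        if self.modulation_ratio <= 0:
            raise ValueError("modulation ratio must be positive")
        if self.n_years < 1:
            raise ValueError("record must span at least one year")
        for lo, hi, step, name in (
            (self.lat_min, self.lat_max, self.lat_step, "lat"),
            (self.lon_min, self.lon_max, self.lon_step, "lon"),
        ):
            if hi <= lo or step <= 0:
                raise ValueError(f"invalid {name} extent")
            n = (hi - lo) / step
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} step does not divide the extent exactly")

    @property
    def lat(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.lat_step))
        return self.lat_min + self.lat_step * (np.arange(n) + 0.5)

    @property
    def lon(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.lon_step))
        return self.lon_min + self.lon_step * (np.arange(n) + 0.5)


@dataclass
class ImplantSpec:
    """One heatwave to implant: a box footprint, dates and a peak amplitude.

    The temporal profile is a linear ramp up over ``ramp_up`` of the duration,
    a plateau at ``amplitude_C``, and a linear ramp down over ``ramp_down``.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    start: int              # 0-based ordinal day in the record
    duration_d: int
    amplitude_C: float
    ramp_up: float = 0.2
    ramp_down: float = 0.2

    def __post_init__(self) -> None:
        if self.duration_d < 1:
            raise ValueError("duration must be at least 1 day")
        if not np.isfinite(self.amplitude_C):
            raise ValueError("amplitude must be finite")

    @property
    def end(self) -> int:
        return self.start + self.duration_d - 1

    def cell_mask(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        return (
            (lat[:, None] >= self.lat_min) & (lat[:, None] <= self.lat_max)
            & (lon[None, :] >= self.lon_min) & (lon[None, :] <= self.lon_max)
        )

    def shape(self) -> np.ndarray:
        x = (np.arange(self.duration_d) + 0.5) / self.duration_d
        up = np.clip(x / max(self.ramp_up, 1e-9), 0.0, 1.0)
        down = np.clip((1.0 - x) / max(self.ramp_down, 1e-9), 0.0, 1.0)
        return np.minimum(1.0, np.minimum(up, down))


@dataclass
class SynthFields:
    """Everything :func:`generate_fields` produces."""

    sst: xr.DataArray
    monthly_ssta: xr.DataArray
    enso_index: xr.DataArray            # monthly, unit-std truth index
    enso_loading: xr.DataArray          # °C per index unit
    nitrate: xr.DataArray               # µmol kg-1, climatological
    atmos: xr.Dataset | None = None
    chl: xr.DataArray | None = None     # mg m-3, 8-day composites
    truth: pd.DataFrame | None = None


def _grid_background(cfg: SynthConfig):
    lat, lon = cfg.lat, cfg.lon
    rad = np.deg2rad(lat)
    mean_sst = -1.0 + 29.0 * np.cos(rad) ** 2
    amp = cfg.seasonal_amp_max * np.abs(np.sin(rad))
    peak = np.where(lat >= 0, cfg.sst_peak_doy_nh,
                    cfg.sst_peak_doy_nh - cfg.phase_offset_days)
    noise_peak = np.where(lat >= 0, cfg.noise_peak_doy_nh,
                          cfg.noise_peak_doy_nh - cfg.phase_offset_days)
    return lat, lon, mean_sst, amp, peak, noise_peak


def _seasonal_cycle(cfg: SynthConfig, doy: np.ndarray) -> np.ndarray:
    """Deterministic background SST(t, lat): mean + annual harmonic."""
    _, _, mean_sst, amp, peak, _ = _grid_background(cfg)
    phase = 2 * np.pi * (doy[:, None] - peak[None, :]) / DAYS_PER_YEAR
    return mean_sst[None, :] + amp[None, :] * np.cos(phase)


def _ar1_noise(cfg: SynthConfig, rng: np.random.Generator,
               n_days: int, doy: np.ndarray, nlat: int, nlon: int) -> np.ndarray:
    """Seasonally modulated AR(1) anomalies, shape (time, lat, lon)."""
    _, _, _, _, _, noise_peak = _grid_background(cfg)
    r = cfg.modulation_ratio
    a = (r - 1.0) / (r + 1.0)
    # modulation of the anomaly std, peaking at local mid-summer
    full_doy = np.concatenate([
        (np.arange(-_BURN_DAYS, 0) % DAYS_PER_YEAR) + 1, doy])
    mod = 1.0 + a * np.cos(
        2 * np.pi * (full_doy[:, None] - noise_peak[None, :]) / DAYS_PER_YEAR)
    sigma_innov = cfg.noise_std * np.sqrt(1.0 - cfg.ar1_phi ** 2)
    eps = rng.standard_normal((n_days + _BURN_DAYS, nlat, nlon))
    eps *= (sigma_innov * mod)[:, :, None]
    out = lfilter([1.0], [1.0, -cfg.ar1_phi], eps, axis=0)
    return out[_BURN_DAYS:]


def _enso_index(cfg: SynthConfig, rng: np.random.Generator, n_months: int) -> np.ndarray:
    innov = rng.standard_normal(n_months + 60) * np.sqrt(1.0 - cfg.enso_rho ** 2)
    idx = lfilter([1.0], [1.0, -cfg.enso_rho], innov)[60:]
    return cfg.enso_amp * idx


def _enso_loading(cfg: SynthConfig) -> np.ndarray:
    lat, lon = cfg.lat, cfg.lon
    lat0, lon0 = cfg.enso_loading_center
    slat, slon = cfg.enso_loading_scale
    dlon = (lon[None, :] - lon0 + 180.0) % 360.0 - 180.0
    return cfg.enso_loading_amp * np.exp(
        -((lat[:, None] - lat0) / slat) ** 2 - (dlon / slon) ** 2)


def _generate_sst(cfg: SynthConfig, ss: np.random.SeedSequence):
    """Deterministic-background + trend + ENSO + AR(1) noise SST cube."""
    time = make_time_axis(cfg.start_year, cfg.n_years)
    doy = time["dayofyear"].astype(float)
    lat, lon = cfg.lat, cfg.lon
    n = len(doy)

    sst_rng, enso_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    background = _seasonal_cycle(cfg, doy)[:, :, None]          # (t, lat, 1)
    trend = (cfg.trend_C_per_decade / 3650.0) * time["ordinal"].astype(float)
    noise = _ar1_noise(cfg, sst_rng, n, time["dayofyear"].astype(float),
                       len(lat), len(lon))

    n_months = cfg.n_years * 12
    idx_monthly = _enso_index(cfg, enso_rng, n_months)
    month_centers = _month_center_ordinals(cfg)
    idx_daily = np.interp(time["ordinal"].astype(float), month_centers, idx_monthly)
    loading = _enso_loading(cfg)

    data = (background + trend[:, None, None]
            + loading[None, :, :] * idx_daily[:, None, None] + noise)
    sst = xr.DataArray(
        data.astype(np.float32),
        dims=("time", "lat", "lon"),
        coords={
            "time": time["ordinal"],
            "year": ("time", time["year"]),
            "dayofyear": ("time", time["dayofyear"]),
            "month": ("time", time["month"]),
            "lat": lat, "lon": lon,
        },
        name="sst",
        attrs={"units": "degC", "start_year": cfg.start_year,
               "calendar": "noleap"},
    )
    idx_da = xr.DataArray(
        idx_monthly, dims=("month_time",),
        coords={"month_time": np.arange(n_months),
                "myear": ("month_time", cfg.start_year + np.arange(n_months) // 12),
                "mmonth": ("month_time", np.arange(n_months) % 12 + 1)},
        name="enso_index")
    loading_da = xr.DataArray(loading, dims=("lat", "lon"),
                              coords={"lat": lat, "lon": lon},
                              name="enso_loading",
                              attrs={"units": "degC per index unit"})
    return sst, idx_da, loading_da


def _month_center_ordinals(cfg: SynthConfig) -> np.ndarray:
    from ._calendar import MONTH_LENGTHS, MONTH_START_DOY
    starts = np.concatenate([
        y * DAYS_PER_YEAR + (MONTH_START_DOY - 1) for y in range(cfg.n_years)])
    lengths = np.tile(MONTH_LENGTHS, cfg.n_years)
    return starts + (lengths - 1) / 2.0


def _monthly_means(sst: xr.DataArray, cfg: SynthConfig) -> xr.DataArray:
    from ._calendar import MONTH_LENGTHS, MONTH_START_DOY
    starts = np.concatenate([
        y * DAYS_PER_YEAR + (MONTH_START_DOY - 1) for y in range(cfg.n_years)])
    sums = np.add.reduceat(sst.values, starts, axis=0)
    means = sums / np.tile(MONTH_LENGTHS, cfg.n_years)[:, None, None]
    n_months = cfg.n_years * 12
    return xr.DataArray(
        means, dims=("month_time", "lat", "lon"),
        coords={"month_time": np.arange(n_months),
                "myear": ("month_time", cfg.start_year + np.arange(n_months) // 12),
                "mmonth": ("month_time", np.arange(n_months) % 12 + 1),
                "lat": sst.lat, "lon": sst.lon},
        name="sst_monthly")


def monthly_anomalies(sst: xr.DataArray, cfg: SynthConfig,
                      base_years: tuple[int, int] | None = None) -> xr.DataArray:
    """Monthly SST anomalies relative to the base-period monthly climatology."""
    mm = _monthly_means(sst, cfg)
    years = mm.myear.values
    if base_years is None:
        base_years = (int(years.min()), int(years.max()))
    in_base = (years >= base_years[0]) & (years <= base_years[1])
    clim = np.empty((12,) + mm.shape[1:])
    for m in range(12):
        clim[m] = mm.values[in_base & (mm.mmonth.values == m + 1)].mean(axis=0)
    anom = mm - clim[mm.mmonth.values - 1]
    anom.name = "ssta_monthly"
    return anom


def _daily_anomaly(sst: xr.DataArray, cfg: SynthConfig) -> np.ndarray:
    """SST minus the deterministic seasonal background (trend retained)."""
    background = _seasonal_cycle(cfg, sst.dayofyear.values.astype(float))
    return sst.values - background[:, :, None]


def _atmos_fields(cfg: SynthConfig, rng: np.random.Generator,
                  sst: xr.DataArray) -> xr.Dataset:
    ssta = _daily_anomaly(sst, cfg)
    n, nlat, nlon = ssta.shape
    phi = 0.7
    data_vars = {}
    for name in DEFAULT_COUPLINGS:  # fixed iteration order keeps draws reproducible
        coef = cfg.couplings.get(name, 0.0)
        std = _ATMOS_NOISE_STD[name]
        eps = rng.standard_normal((n + 120, nlat, nlon)) * std * np.sqrt(1 - phi ** 2)
        noise = lfilter([1.0], [1.0, -phi], eps, axis=0)[120:]
        data_vars[name] = xr.DataArray(
            (_ATMOS_CLIM[name] + coef * ssta + noise).astype(np.float32),
            dims=("time", "lat", "lon"), coords=sst.coords,
            attrs={"units": _ATMOS_UNITS[name]})
    return xr.Dataset(data_vars)


def _composite_starts(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Start ordinals and lengths of the 46 8-day composites per year."""
    per_year = np.arange(0, DAYS_PER_YEAR, 8)          # 46 starts, last is 5 days
    lengths = np.diff(np.append(per_year, DAYS_PER_YEAR))
    starts = np.concatenate([y * DAYS_PER_YEAR + per_year for y in range(cfg.n_years)])
    return starts, np.tile(lengths, cfg.n_years)


def _chl_field(cfg: SynthConfig, rng: np.random.Generator,
               sst: xr.DataArray) -> xr.DataArray:
    lat, lon = cfg.lat, cfg.lon
    ssta = _daily_anomaly(sst, cfg)
    starts, lengths = _composite_starts(cfg)
    ssta8 = np.add.reduceat(ssta, starts, axis=0) / lengths[:, None, None]

    alat = np.abs(lat)
    log_clim = -1.1 + 0.9 * (alat / 90.0)                      # oligotrophic tropics
    seas_amp = 0.15 * (alat / 90.0)
    spring_peak = np.where(lat >= 0, 120.0, 120.0 + cfg.phase_offset_days)
    centers_doy = (starts % DAYS_PER_YEAR) + (lengths - 1) / 2.0
    seasonal = seas_amp[None, :] * np.cos(
        2 * np.pi * (centers_doy[:, None] - spring_peak[None, :]) / DAYS_PER_YEAR)
    coupling = cfg.chl_coupling * np.tanh((alat - cfg.chl_switch_lat) / 10.0)

    phi = 0.5
    eps = rng.standard_normal(ssta8.shape) * cfg.chl_noise_std * np.sqrt(1 - phi ** 2)
    noise = lfilter([1.0], [1.0, -phi], eps, axis=0)
    log_chl = (log_clim[None, :, None] + seasonal[:, :, None]
               + coupling[None, :, None] * ssta8 + noise)
    n_per_year = len(starts) // cfg.n_years
    return xr.DataArray(
        (10.0 ** log_chl).astype(np.float32),
        dims=("time8", "lat", "lon"),
        coords={
            "time8": np.arange(len(starts)),
            "comp_start": ("time8", starts),
            "comp_center": ("time8", starts + (lengths - 1) / 2.0),
            "comp_of_year": ("time8", np.tile(np.arange(1, n_per_year + 1), cfg.n_years)),
            "cyear": ("time8", cfg.start_year + np.arange(len(starts)) // n_per_year),
            "lat": lat, "lon": lon,
        },
        name="chl", attrs={"units": "mg m-3", "start_year": cfg.start_year})


def _nitrate(cfg: SynthConfig) -> xr.DataArray:
    alat = np.abs(cfg.lat)
    nit = 0.3 + 25.0 * (alat / 90.0) ** 2
    return xr.DataArray(
        np.broadcast_to(nit[:, None], (len(cfg.lat), len(cfg.lon))).copy(),
        dims=("lat", "lon"), coords={"lat": cfg.lat, "lon": cfg.lon},
        name="nitrate", attrs={"units": "umol kg-1"})


def generate_fields(cfg: SynthConfig,
                    implant_specs: list[ImplantSpec] | None = None,
                    include_atmos: bool = True,
                    include_chl: bool = True) -> SynthFields:
    """Generate the full synthetic input set.

    When ``implant_specs`` is given, events are implanted into the SST before
    the atmospheric and chlorophyll fields are generated, so the covarying
    fields respond to the implanted anomalies as well as to the stochastic
    background.  Bit-identical for a fixed config (the ``include_*`` switches
    do not perturb the SST stream).
    """
    ss = np.random.SeedSequence(cfg.seed)
    ss_sst, ss_atmos, ss_chl = ss.spawn(3)
    sst, enso_index, loading = _generate_sst(cfg, ss_sst)

    truth = None
    if implant_specs:
        sst, truth = implant_events(sst, implant_specs)

    baseline = (cfg.start_year + 1, min(cfg.start_year + 30,
                                        cfg.start_year + cfg.n_years - 1))
    monthly_ssta = monthly_anomalies(sst, cfg, base_years=baseline)
    atmos = (_atmos_fields(cfg, np.random.default_rng(ss_atmos), sst)
             if include_atmos else None)
    chl = (_chl_field(cfg, np.random.default_rng(ss_chl), sst)
           if include_chl else None)
    return SynthFields(sst=sst, monthly_ssta=monthly_ssta,
                       enso_index=enso_index, enso_loading=loading,
                       nitrate=_nitrate(cfg), atmos=atmos, chl=chl, truth=truth)


def implant_events(sst: xr.DataArray,
                   specs: list[ImplantSpec]) -> tuple[xr.DataArray, pd.DataFrame]:
    """Add events to an SST cube; returns the modified cube and a truth table.

    Specs whose footprints overlap in both space and time are rejected — the
    truth table must stay unambiguous for parameter-recovery tests.
    """
    lat, lon = sst.lat.values, sst.lon.values
    n_time = sst.sizes["time"]
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            a, b = specs[i], specs[j]
            space = (a.cell_mask(lat, lon) & b.cell_mask(lat, lon)).any()
            time_olap = a.start <= b.end and b.start <= a.end
            if space and time_olap:
                raise ValueError(
                    f"implant specs {i} and {j} overlap in both space and time")

    out = sst.values.copy()
    start_year = int(sst.attrs.get("start_year", 0))
    rows = []
    for k, spec in enumerate(specs):
        mask = spec.cell_mask(lat, lon)
        if not mask.any():
            raise ValueError(f"implant spec {k} footprint contains no grid cells")
        if spec.start < 0 or spec.end >= n_time:
            raise ValueError(f"implant spec {k} dates fall outside the record")
        profile = spec.amplitude_C * spec.shape()
        sl = slice(spec.start, spec.end + 1)
        out[sl] += profile[:, None, None] * mask[None, :, :]
        rows.append({
            "event_id": k,
            "lat_min": spec.lat_min, "lat_max": spec.lat_max,
            "lon_min": spec.lon_min, "lon_max": spec.lon_max,
            "start": spec.start, "end": spec.end,
            "start_date": ordinal_to_date_str(spec.start, start_year),
            "end_date": ordinal_to_date_str(spec.end, start_year),
            "duration_d": spec.duration_d,
            "amplitude_C": spec.amplitude_C,
        })
    truth = pd.DataFrame(rows, columns=[
        "event_id", "lat_min", "lat_max", "lon_min", "lon_max", "start", "end",
        "start_date", "end_date", "duration_d", "amplitude_C"])
    new = sst.copy()
    new.values = out
    return new, truth


def trend_duration_experiment(cfg: SynthConfig,
                              trend_rates: list[float],
                              replicates: int,
                              baseline_years: tuple[int, int] | None = None,
                              min_duration: int = 5,
                              max_gap: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean longest event duration as a function of linear warming trend.

    Single-cell records are simulated at each trend rate; thresholds are built
    from a fixed baseline window regardless of trend, mirroring a fixed
    climatological baseline in a warming record.  Returns a per-rate summary
    (mean longest duration with Monte-Carlo standard error) and a per-replicate
    detail table (longest duration and the central year of that event).
    """
    from dataclasses import replace
    from .climatology import build_climatology
    from .detection import detect_events_grid

    if replicates < 1:
        raise ValueError("need at least one replicate")
    if baseline_years is None:
        baseline_years = (cfg.start_year + 1, cfg.start_year + 30)

    base = replace(cfg, lat_min=40.0, lat_max=40.0 + cfg.lat_step,
                   lon_min=180.0, lon_max=180.0 + cfg.lon_step,
                   enso_loading_amp=0.0)
    master = np.random.SeedSequence(cfg.seed)
    detail = []
    for rate in trend_rates:
        children = master.spawn(replicates)
        for rep, child in enumerate(children):
            rcfg = replace(base, trend_C_per_decade=rate)
            sst, _, _ = _generate_sst(rcfg, child)
            clim = build_climatology(sst, baseline=baseline_years)
            events = detect_events_grid(sst, clim, min_duration=min_duration,
                                        max_gap=max_gap)
            if len(events):
                longest = events.loc[events.duration_d.idxmax()]
                dur = int(longest.duration_d)
                center = int((longest.start + longest.end) // 2)
                cyear = cfg.start_year + center // DAYS_PER_YEAR
            else:
                dur, cyear = 0, np.nan
            detail.append({"trend_C_per_decade": rate, "replicate": rep,
                           "longest_d": dur, "central_year": cyear})
    detail = pd.DataFrame(detail)
    summary = (detail.groupby("trend_C_per_decade")["longest_d"]
               .agg(mean_longest_d="mean",
                    mc_se=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
               .reset_index())
    return summary, detail
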