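# Methods

This note documents the models, conventions and design choices behind
`mhwx`: what each stage computes, which parameters matter and why their
defaults were chosen, what the synthetic-data generator does and does not
emulate, and the numerical details a user must know to reproduce results.

## Calendar

All synthetic analyses run on a 365-day (no-leap) year, which removes
leap-day bookkeeping from event arithmetic. Real-data inputs with a
`datetime64` axis are folded onto the same climatological year: Feb 29
observations are pooled with Feb 28 (day-of-year 59) and later dates shift
down by one, so Mar 1 is always day 60. Time inside the package is an
integer ordinal day; date strings are derived views.

## Climatology and threshold

For each grid cell and day-of-year *d*, every baseline observation whose
day-of-year lies within ±5 days of *d* (an 11-day window, circular across
the year boundary) is pooled over all baseline years. The climatological
mean is the mean of this pool and the threshold PC90 is its 90th
percentile. Both fields are then smoothed along day-of-year with a centred,
unweighted, circularly wrapped 31-day moving average — the same filter for
mean and threshold, so the severity denominator stays consistent.

Numerical conventions that change results at small sample sizes and are
therefore recorded as attributes on the output:

- **Percentile definition** — linear interpolation between order statistics
  by default (`interpolation="linear"`); nearest-rank is available and
  yields visibly different thresholds with few baseline years.
- **Smoothing kernel** — a boxcar. Its effect on the annual harmonic is the
  Dirichlet factor sin(31π/365)/(31 sin(π/365)) ≈ 0.9882, i.e. the
  climatological summer maximum is reduced by roughly one percent of the
  annual cycle amplitude; the 11-day pooling contributes a further ≈ 0.9985.
  The unsmoothed fields are retained in the output (`*_raw`) so this
  attenuation can be measured directly.
- **Degeneracy** — cells/days where PC90 does not exceed the mean
  (zero-variance input, e.g. ice-filled or constant series) are flagged in a
  mask; severity is masked there rather than returning infinities.

`remove_seasonal_trend` fits, per cell and day-of-year (with the same
11-day pooling), an OLS slope of SST against year and removes the fitted
anomaly about the record-mean year. This supports sensitivity analyses of
record timing to the secular warming trend; the main pipeline deliberately
does **not** detrend, treating thermal thresholds as fixed.

## Detection and severity

An event is a maximal run of days with SST **strictly above** PC90 lasting
at least `min_duration = 5` days. Two qualifying runs separated by at most
`max_gap = 1` sub-threshold days merge into one event ("below threshold for
fewer than 2 days"); a common variant with 2-day gaps is a config switch.
Gap days count toward the duration and contribute their (possibly negative)
anomaly to the cumulative intensity — an event is a single dated span.
Missing days are treated as below threshold and break runs. Metrics use
anomalies about the *smoothed* climatological mean, self-consistent with
the threshold.

Severity S = (SST − clim)/(PC90 − clim) is dimensionless and scale-free
(invariant under joint affine transformation of SST, climatology and
threshold). Categories: moderate 1 < S ≤ 2, strong 2 < S ≤ 3, severe
3 < S ≤ 4, extreme S ≥ 4; category 0 denotes no heatwave. Heatwave *state*
— used for categories and spatial extent — exists only while a detected
event is in progress: `event_state_mask` excludes sub-5-day exceedances,
which matters because the threshold is exceeded on ~10% of days by
construction and transient exceedances would otherwise attach spurious
cells to contiguous events.

## Spatial extent

Cell areas use the exact spherical band formula
A = R² Δλ (sin φ_top − sin φ_bottom) with R = 6371 km, so a global grid
telescopes to 4πR² to machine precision. "Connected in any direction" is
read as 8-connectivity (diagonals included; 4-connectivity is a config
switch), with seam-free wrapping across the longitude boundary and no
wrapping over the poles. Components are daily snapshots: no day-to-day
identity tracking is attempted, because extent varies strongly on daily
timescales through merger and splitting. The daily largest-event series can
exclude components intersecting a configured box (default equatorial
central/eastern Pacific, 5°S–5°N east of 170°E) to separate basin-scale
ENSO warming from other events.

## Records, seasonality, extreme regions

Record maps take per-cell argmaxima over events (longest duration, largest
cumulative intensity, maximum intensity, maximum severity), ties resolved
to the earliest event. Record seasonality is the area-weighted fraction of
each hemisphere (poleward of ±5°) whose record date falls in each calendar
month; fractions are renormalized after any phase-based exclusion so they
always sum to 1 per hemisphere.

A cell is an extreme-region **candidate** when its most severe recorded day
lies within the span of its largest-cumulative-intensity event — the
intersection of "most severe" and "most accumulated". Regions are either
user-supplied polygons intersected with the candidate mask (for fidelity to
hand-drawn analyses) or, by default, a deterministic fallback: connected
components (8-connectivity, dateline-aware) of candidate cells whose record
dates agree within `date_window_d = 90` days, keeping components of at
least `min_cells = 4` cells. The fallback replaces an inherently manual
delineation step with a stated, reproducible rule; it makes no claim of
matching any particular hand-drawn polygon set.

Each region is characterized by four daily series: (i) the fraction of
region area in heatwave state above a severity level, (ii) the largest
contiguous event area (at S > 1 and S > 2) intersecting the region,
(iii) that event's area-integrated SSTA, and (iv) the number of member
cells at their record-severity day. The **core period** is the longest run
of days with (i) > `f_min = 0.3` and the S > 1 contiguous area above
`r_min = 0.5` of its own maximum; both thresholds are free parameters
chosen to bracket the plateau of a coherent basin-scale event, and the
summary maxima (areas and areal intensities with dates, member-cell
duration median and interquartile range) are evaluated within the core.
The region **peak** is the core day maximizing area-weighted region-mean
severity.

## ENSO conditioning

The Niño3.4-like index is the area-weighted monthly SST anomaly over
5°S–5°N, 170°W–120°W, standardized by the base-period standard deviation
(default: the climatology baseline; configurable, since observational
standardizations often use longer records). |index| > 1 marks moderate and
|index| > 2 strong phases, sign separating El Niño from La Niña. Record
attribution assigns each cell's record day (or, for durations, the central
day) to the month containing it. The regression map is the per-cell OLS
slope of monthly SSTA on the standardized index (°C per index s.d.), masked
below 24 overlapping months.

## Driver composites

For each region and driver field (sea-level pressure, 10-m wind speed and
zonal wind, downward shortwave and longwave, latent and sensible heat
flux), the area-weighted region-mean daily series is averaged over a fixed
calendar window relative to the peak: **pre** = 6 to 2 weeks before (days
−42..−15) and **post** = 2 to 6 weeks after (days +15..+42). A 3-week
variant (6-to-3 weeks / 3-to-6 weeks) is provided as
`PRE_WINDOW_SHORT`/`POST_WINDOW_SHORT`; the 4-week definition is the
default. The anomaly is taken against the mean of the *same calendar
window* across all years with at least 75% day coverage and normalized by
the across-year standard deviation of that window. Flags rank the
**absolute** anomaly across years: the ⌊n/10⌋ most extreme years are "top
decile" (4 of 41 years) and the single most extreme is a "record", so
record implies top decile and the null flag rate is ~10% by construction.
Fluxes are signed downward-positive, so "suppressed latent heat loss"
appears as a positive latent anomaly.

## Chlorophyll response

Chlorophyll anomalies are computed in log10 space by default (the
concentration distribution is strongly skewed; a linear-space option
exists and reported results must name the choice). The regional anomaly
series is the area-weighted region mean minus its composite-of-year
climatology; the response is the mean anomaly over the three 8-day
composites covering the 24-day window centred on the peak (the composite
containing the peak plus both neighbours — the maximal-overlap triple),
divided by the standard deviation of the regional anomaly series over the
full record. Events predating the chlorophyll record return a null
response with a reason rather than an error.

Significance is assessed two ways. Across regions, an exact one-sided
binomial test on the count of negative responses under p₀ = 0.5. Per
region, a Monte-Carlo null: window anomalies recomputed at `n_resamples =
10,000` (configurable, seeded) centres drawn from composites that do not
overlap the region's events, with the add-one empirical two-sided p-value
p = (1 + #{|null| ≥ |obs|})/(n + 1); anomalies are zero-centred by
construction, which is what makes the absolute-value form two-sided.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
ocean dynamics:

- **SST** = latitudinal mean state + annual harmonic (amplitude growing
  poleward, hemispheres phase-opposed by 182.5 days) + optional linear
  trend + ENSO loading × index + AR(1) noise. Defaults: 36-year record
  (1982–2017 analogue) with a 1983–2012-analogue baseline, daily AR(1)
  coefficient 0.85 and stationary anomaly std 0.7 °C (mid-latitude-like
  persistence and variance), trend 0.2 °C/decade (satellite-era ocean
  surface warming scale).
- **Seasonal variance modulation** — the innovation std is modulated by a
  smooth sinusoid in day-of-year peaking at local mid-summer (day 197 NH),
  *before* the climatological SST maximum (day 226 NH), with a
  summer:winter std ratio of 1.5 by default. This is a phenomenological
  stand-in for shallow summer mixed layers amplifying SST variability; no
  mixed-layer depth is simulated.
- **ENSO-like index** — a monthly AR(1) process (autocorrelation 0.9, unit
  std) interpolated to daily and imprinted through a Gaussian equatorial
  loading pattern (centre 0°N 210°E, e-folding 12° × 50°, 1 °C per index
  unit). There is no phase-locking to the calendar and no ENSO dynamics.
- **Drivers and chlorophyll** — each field is a climatology plus a *linear*
  coupling to the local SST anomaly plus independent AR(1) noise. Coupling
  signs encode the expected physics (high pressure and suppressed winds
  over warm anomalies; chlorophyll response negative equatorward of ~40°
  latitude and positive poleward, via a tanh transition); magnitudes are
  chosen for testability, as no quantitative coupling strengths are
  established for this purpose. Nitrate is a time-invariant field
  increasing quadratically with |latitude| (oligotrophic tropics).
- **Implanted events** add a ramp–plateau–ramp anomaly (default 20% ramps)
  over a box footprint, with overlap rejection and a truth table for
  parameter-recovery tests. Implanting then subtracting the same
  specification restores the field exactly, and the covarying fields are
  generated *after* implanting so driver/chlorophyll responses to implants
  are recoverable.

Because couplings are linear and instantaneous, passing tests demonstrate
that the pipeline *recovers imposed structure*; they say nothing about
lead–lag relationships, nonlinear feedbacks, spatial propagation, sea ice,
land masks or observational error in real products. The generator's value
is that every downstream statistic has a known expected sign or value.

## Problem sizes

Test and verification runs use coarse grids chosen to exercise every code
path at interactive cost: typically 5–20° spacing (a few hundred to ~1200
cells), 10–36-year records, 200 replicates for the duration-vs-trend curve,
1000 random series for detection-oracle equivalence, 500 masks for labeling
equivalence, and 500–1000 synthetic regions for the null calibrations.
All of these are package choices; every routine accepts arbitrary grid
resolutions.

## Known limitations

- No heat-budget or subsurface analysis; drivers are composited, not
  attributed.
- Ekman transport is not computed (no stress formulation is adopted).
- Contiguous events have no temporal identity; "largest event" is a daily
  snapshot.
- The automatic region rule is a reproducible stand-in for manual
  delineation, and its `f_min`/`r_min`/`date_window_d` parameters should be
  varied when conclusions depend on region boundaries.
- NetCDF output uses the NetCDF3 classic model (via xarray's scipy
  backend): no compression, no 64-bit integers.
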