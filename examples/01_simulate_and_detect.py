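"""Simulate a gridded SST record and detect marine heatwaves.

Builds a 10-year synthetic record, computes the day-of-year climatology and
seasonally varying 90th-percentile threshold over its first 8 full years,
detects per-cell events, and prints the per-cell record statistics.
"""

import mhwx

cfg = mhwx.SynthConfig(lat_min=-60, lat_max=60, lat_step=10,
                       lon_min=0, lon_max=360, lon_step=20,
                       n_years=10, seed=42)
fields = mhwx.generate_fields(cfg, include_atmos=False, include_chl=False)
clim = mhwx.build_climatology(fields.sst, baseline=(1983, 1990))
events = mhwx.detect_events_grid(fields.sst, clim)
rollup = mhwx.event_metrics_rollup(events)

print(f"grid cells: {fields.sst.sizes['lat'] * fields.sst.sizes['lon']}")
print(f"events detected: {len(events)}")
print(f"mean events per cell: {len(events) / len(rollup):.1f}")
print(f"median event duration: {events.duration_d.median():.0f} d")
print(f"longest event anywhere: {events.duration_d.max()} d")
print(f"largest cumulative intensity: {events.cum_int_Cd.max():.1f} degC d")
print(f"cells reaching strong (category 2+): "
      f"{(rollup.max_cat >= 2).mean() * 100:.0f}%")

# Every cell sees events (the threshold is exceeded ~10% of days by
# construction); duration and cumulative intensity identify the standouts.
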