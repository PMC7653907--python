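import numpy as np
import pytest

import mhwx


@pytest.fixture(scope="session")
def small_config():
    """A quick 10-year, coarse-grid record used by several modules."""
    return mhwx.SynthConfig(
        lat_min=-60, lat_max=60, lat_step=10,
        lon_min=0, lon_max=360, lon_step=20,
        n_years=10, noise_std=0.3, trend_C_per_decade=0.0,
        enso_loading_amp=0.3, seed=7)


@pytest.fixture(scope="session")
def implant_scenario(small_config):
    """Fields with one large implanted event after the baseline, plus the
    derived climatology, severity, events and record maps."""
    spec = mhwx.ImplantSpec(lat_min=10, lat_max=40, lon_min=100, lon_max=180,
                            start=9 * 365 + 60, duration_d=90, amplitude_C=3.0)
    fields = mhwx.generate_fields(small_config, implant_specs=[spec])
    clim = mhwx.build_climatology(fields.sst, baseline=(1983, 1990))
    sev = mhwx.severity(fields.sst, clim)
    ssta = fields.sst - clim["clim_mean"].values[
        fields.sst["dayofyear"].values - 1]
    events = mhwx.detect_events_grid(fields.sst, clim)
    from mhwx.detection import event_state_mask
    ev_mask = event_state_mask(events, sev["severity"].shape[0],
                               sev["severity"].shape[1],
                               sev["severity"].shape[2])
    rollup = mhwx.event_metrics_rollup(events)
    records = mhwx.record_maps(rollup, fields.sst["lat"].values,
                               fields.sst["lon"].values, start_year=1982)
    areas = mhwx.cell_areas(fields.sst["lat"].values,
                            small_config.lat_step, small_config.lon_step)
    return {"config": small_config, "spec": spec, "fields": fields,
            "clim": clim, "sev": sev, "ssta": ssta, "events": events,
            "event_mask": ev_mask, "rollup": rollup, "records": records,
            "areas": areas}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
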