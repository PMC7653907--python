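"""Chlorophyll response: windowing, sign test, Monte-Carlo null, nitrate."""

import numpy as np
import pytest

import mhwx
from mhwx.chl import _window_comps, sign_binomial_test

from _oracles import exact_binomial_tail


class TestBinomialSignTest:
    def test_all_four_negative(self):
        assert sign_binomial_test(4, 4) == pytest.approx(0.0625)

    def test_headline_38_of_52_is_significant(self):
        p = sign_binomial_test(38, 52)
        assert p == pytest.approx(exact_binomial_tail(38, 52), rel=1e-12)
        assert p < 0.001

    def test_even_split_is_not_significant(self):
        p = sign_binomial_test(26, 52)
        assert p == pytest.approx(exact_binomial_tail(26, 52), rel=1e-12)
        assert 0.5 < p < 0.6

    def test_agrees_with_exact_summation_up_to_n_60(self):
        for n in (1, 7, 23, 41, 60):
            for k in range(0, n + 1, max(1, n // 6)):
                assert sign_binomial_test(k, n) == pytest.approx(
                    exact_binomial_tail(k, n), rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sign_binomial_test(0, 0)
        with pytest.raises(ValueError):
            sign_binomial_test(5, 4)


class TestWindowSelection:
    def test_window_is_composite_containing_peak_plus_neighbours(self):
        cfg = mhwx.SynthConfig(lat_min=0, lat_max=20, lat_step=10,
                               lon_min=0, lon_max=40, lon_step=20,
                               n_years=3, seed=0)
        f = mhwx.generate_fields(cfg, include_atmos=False)
        peak = 400                          # inside year 2
        comps = _window_comps(f.chl, peak)
        starts = f.chl["comp_start"].values
        t = comps[1]
        assert starts[t] <= peak < starts[t + 1]
        assert comps == (t - 1, t, t + 1)

    def test_peak_before_record_returns_none_response(self):
        cfg = mhwx.SynthConfig(lat_min=0, lat_max=20, lat_step=10,
                               lon_min=0, lon_max=40, lon_step=20,
                               n_years=3, seed=0)
        f = mhwx.generate_fields(cfg, include_atmos=False)
        chl_late = f.chl.isel(time8=slice(50, None))    # record starts later
        region = mhwx.ExtremeRegion(0, np.array([[0, 0]]), lat_center=5.0)
        areas = np.ones(2)
        resp = mhwx.chl_mhw_response(chl_late, region, areas, peak=10)
        assert not resp.ok
        assert resp.reason is not None


class TestResponseRecovery:
    def test_zero_anomaly_in_window_gives_zero(self, rng):
        cfg = mhwx.SynthConfig(lat_min=0, lat_max=20, lat_step=10,
                               lon_min=0, lon_max=40, lon_step=20,
                               n_years=5, chl_noise_std=0.1,
                               chl_coupling=0.0, seed=4)
        f = mhwx.generate_fields(cfg, include_atmos=False)
        region = mhwx.ExtremeRegion(0, np.array([[0, 0], [1, 0]]),
                                    lat_center=10.0)
        areas = mhwx.cell_areas(np.array([5.0, 15.0]), 10.0, 20.0)
        anom, std = mhwx.regional_chl_anomalies(f.chl, region.cells, areas)
        # anomaly series is centred by construction
        assert abs(np.nanmean(anom)) < 0.05
        assert std > 0

    def test_implanted_suppression_recovered(self):
        """A tropical implant with negative chlorophyll coupling yields a
        clearly negative normalized response."""
        cfg = mhwx.SynthConfig(lat_min=-30, lat_max=30, lat_step=10,
                               lon_min=0, lon_max=360, lon_step=30,
                               n_years=10, noise_std=0.2, chl_coupling=0.4,
                               trend_C_per_decade=0.0, enso_loading_amp=0.0,
                               chl_noise_std=0.05, seed=13)
        spec = mhwx.ImplantSpec(-10, 10, 90, 180, start=9 * 365 + 100,
                                duration_d=60, amplitude_C=3.0)
        f = mhwx.generate_fields(cfg, implant_specs=[spec],
                                 include_atmos=False)
        lat = f.chl["lat"].values
        mask = spec.cell_mask(lat, f.chl["lon"].values)
        region = mhwx.ExtremeRegion(0, np.argwhere(mask),
                                    lat_center=float(lat[np.argwhere(mask)[:, 0]].mean()))
        areas = mhwx.cell_areas(lat, 10.0, 30.0)
        peak = spec.start + spec.duration_d // 2
        resp = mhwx.chl_mhw_response(f.chl, region, areas, peak,
                                     nitrate=f.nitrate)
        assert resp.ok
        assert resp.norm_anom < -1.0
        assert resp.sign == -1


class TestMonteCarloNull:
    def _null_setup(self, rng, n=920):
        anom = rng.standard_normal(n)
        std = anom.std(ddof=1)
        in_event = np.zeros(n, dtype=bool)
        in_event[500:510] = True
        return anom, std, in_event

    def test_zero_observation_has_p_near_one(self, rng):
        anom, std, in_event = self._null_setup(rng)
        _, p = mhwx.monte_carlo_null(anom, std, in_event, observed=0.0,
                                     n_resamples=2000, seed=1)
        assert p > 0.9

    def test_extreme_observation_hits_add_one_bound(self, rng):
        anom, std, in_event = self._null_setup(rng)
        _, p = mhwx.monte_carlo_null(anom, std, in_event, observed=-50.0,
                                     n_resamples=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_deterministic_under_fixed_seed(self, rng):
        anom, std, in_event = self._null_setup(rng)
        null1, p1 = mhwx.monte_carlo_null(anom, std, in_event, 0.7,
                                          n_resamples=500, seed=9)
        null2, p2 = mhwx.monte_carlo_null(anom, std, in_event, 0.7,
                                          n_resamples=500, seed=9)
        assert p1 == p2
        np.testing.assert_array_equal(null1, null2)

    def test_converges_with_resample_count(self, rng):
        anom, std, in_event = self._null_setup(rng, n=3000)
        _, p1 = mhwx.monte_carlo_null(anom, std, in_event, 1.2,
                                      n_resamples=10_000, seed=3)
        _, p2 = mhwx.monte_carlo_null(anom, std, in_event, 1.2,
                                      n_resamples=100_000, seed=4)
        assert abs(p1 - p2) < 0.01

    def test_too_few_candidates_rejected(self, rng):
        anom = rng.standard_normal(120)
        in_event = np.ones(120, dtype=bool)
        in_event[:50] = False
        with pytest.raises(ValueError):
            mhwx.monte_carlo_null(anom, 1.0, in_event, 0.0)


class TestNitrateRelation:
    def _resp(self, rid, anom, lat, nit):
        return mhwx.ChlResponse(rid, anom, lat, nit, int(np.sign(anom)),
                                (0, 1, 2))

    def test_empty_input(self):
        table, summary = mhwx.nitrate_relation([])
        assert table.empty and summary == {}

    def test_proportional_anomalies_give_perfect_rank_correlation(self):
        responses = [self._resp(i, 0.1 * n, 30.0, n)
                     for i, n in enumerate([1.0, 5.0, 10.0, 20.0])]
        _, summary = mhwx.nitrate_relation(responses)
        assert summary["spearman_nitrate_anom"] == pytest.approx(1.0)

    def test_tropical_suppression_recovered_from_generator(self):
        """Low-latitude regions with the generator's negative chlorophyll
        coupling all respond negatively; rank correlation with nitrate is
        positive (nitrate rises poleward where the coupling flips sign)."""
        cfg = mhwx.SynthConfig(lat_min=-60, lat_max=60, lat_step=10,
                               lon_min=0, lon_max=360, lon_step=30,
                               n_years=10, noise_std=0.2, chl_coupling=0.5,
                               chl_noise_std=0.04,
                               trend_C_per_decade=0.0, enso_loading_amp=0.0,
                               seed=17)
        specs = [mhwx.ImplantSpec(la, la + 10, 90, 150, start=9 * 365 + 100,
                                  duration_d=60, amplitude_C=3.0)
                 for la in (-15, 5, 45)] + \
                [mhwx.ImplantSpec(-55, -45, 210, 270, start=9 * 365 + 100,
                                  duration_d=60, amplitude_C=3.0)]
        f = mhwx.generate_fields(cfg, implant_specs=specs,
                                 include_atmos=False)
        lat = f.chl["lat"].values
        areas = mhwx.cell_areas(lat, 10.0, 30.0)
        responses = []
        for i, s in enumerate(specs):
            cells = np.argwhere(s.cell_mask(lat, f.chl["lon"].values))
            region = mhwx.ExtremeRegion(i, cells,
                                        lat_center=float(lat[cells[:, 0]].mean()))
            peak = s.start + s.duration_d // 2
            responses.append(mhwx.chl_mhw_response(f.chl, region, areas,
                                                   peak, nitrate=f.nitrate))
        table, summary = mhwx.nitrate_relation(responses)
        assert summary["frac_negative_tropical"] == 1.0
        assert summary["frac_negative_extratropical"] < 1.0
        assert summary["spearman_nitrate_anom"] > 0
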