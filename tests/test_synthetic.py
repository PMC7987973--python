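import dataclasses

import numpy as np
import pandas as pd
import pytest

from heatresp import (
    SynthConfig,
    generate_flux,
    generate_moisture,
    generate_site,
    generate_temperature,
    ground_truth_all_conditions,
    ground_truth_exceedance,
    moisture_scaling,
    temperature_mean,
)
from heatresp.climatology import HOURS_PER_YEAR


def quiet_cfg(**overrides):
    """Constant-driver configuration: no harmonics, no noise, no episodes."""
    base = dict(
        seed=0,
        climatology_years=0,
        study_hours=240,
        t_seasonal_amp=0.0,
        t_diurnal_amp=0.0,
        t_ar1_sd=0.0,
        heat_episode_rate=0.0,
        precip_rate=0.0,
        dew_amp=0.0,
        noise_sd=0.0,
        missing_frac=0.0,
    )
    base.update(overrides)
    return SynthConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("t_ar1_coef", 1.0),
            ("q10", 0.0),
            ("missing_frac", 1.0),
            ("sm_floor", 0.5),  # above default ceiling 0.37
            ("noise_sd", -0.1),
            ("subhourly_per_hour", 0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValueError):
            SynthConfig(**{field: value})


class TestTemperature:
    def test_zero_amplitude_zero_noise_is_constant(self):
        temp = generate_temperature(quiet_cfg())
        assert (temp.data["tair"] == 17.0).all()

    def test_same_seed_is_identical(self):
        cfg = SynthConfig(seed=5, climatology_years=1, study_hours=0)
        a = generate_temperature(cfg)
        b = generate_temperature(cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        a = generate_temperature(SynthConfig(seed=1, climatology_years=1, study_hours=0))
        b = generate_temperature(SynthConfig(seed=2, climatology_years=1, study_hours=0))
        assert not np.allclose(a.data["tair"], b.data["tair"])

    def test_cell_means_match_analytic_expectation(self):
        """Per-(month,hour) sample means of a 30-yr record agree with the
        closed-form mean function plus the expected episode contribution."""
        cfg = SynthConfig(seed=0, climatology_years=30, study_hours=0)
        temp = generate_temperature(cfg)
        idx = temp.data.index
        episode_mean = (
            cfg.heat_episode_rate
            * cfg.heat_episode_mean_hours
            * cfg.heat_episode_boost
            / HOURS_PER_YEAR
        )
        expected = temperature_mean(cfg, idx) + episode_mean
        dev = (
            pd.Series(temp.data["tair"].to_numpy() - expected, index=idx)
            .groupby([idx.month, idx.hour])
            .mean()
        )
        assert np.abs(dev.to_numpy()).max() < 0.5


class TestMoisture:
    def test_no_precip_no_dew_decays_to_floor(self):
        cfg = quiet_cfg(study_hours=2000, sm_init=0.35)
        sm = generate_moisture(cfg, generate_temperature(cfg)).data["sm"].to_numpy()
        assert sm[0] > cfg.sm_floor
        assert (np.diff(sm) <= 1e-12).all()
        assert sm[-1] == pytest.approx(cfg.sm_floor, abs=1e-6)

    def test_jumps_clipped_at_ceiling(self):
        cfg = quiet_cfg(precip_rate=0.5, sm_jump=0.5, study_hours=2000)
        sm = generate_moisture(cfg, generate_temperature(cfg)).data["sm"].to_numpy()
        assert sm.max() <= cfg.sm_ceiling + 1e-12
        assert np.isclose(sm.max(), cfg.sm_ceiling)

    def test_long_run_mean_stable_across_realisations(self):
        cfg = SynthConfig(seed=0, climatology_years=0, study_hours=300_000)
        a = generate_moisture(cfg, generate_temperature(cfg)).data["sm"].mean()
        cfg2 = dataclasses.replace(cfg, seed=104729)
        b = generate_moisture(cfg2, generate_temperature(cfg2)).data["sm"].mean()
        assert a == pytest.approx(b, abs=0.005)

    def test_values_within_physical_bounds(self, default_cfg):
        temp = generate_temperature(default_cfg, n_hours=20_000)
        sm = generate_moisture(default_cfg, temp).data["sm"].to_numpy()
        assert sm.min() >= default_cfg.sm_floor
        assert sm.max() <= default_cfg.sm_ceiling


class TestFlux:
    def test_q10_one_no_noise_is_reference_rate(self):
        cfg = quiet_cfg(q10=1.0)
        temp = generate_temperature(cfg)
        flux = generate_flux(cfg, temp)  # no moisture: g = 1
        assert np.allclose(flux.data["rs"], cfg.rs_ref)

    def test_q10_doubles_per_10_degrees(self):
        cfg = quiet_cfg(q10=2.0, t_mean=27.0, t_ref=17.0)
        flux = generate_flux(cfg, generate_temperature(cfg))
        assert np.allclose(flux.data["rs"], 2.0 * cfg.rs_ref)

    def test_moisture_scaling_shape(self, default_cfg):
        cfg = default_cfg
        assert moisture_scaling(cfg, np.array([cfg.sm_floor]))[0] == pytest.approx(cfg.g_min)
        assert moisture_scaling(cfg, np.array([cfg.sm_sat]))[0] == pytest.approx(1.0)
        assert moisture_scaling(cfg, np.array([cfg.sm_ceiling]))[0] == pytest.approx(1.0)
        mid = (cfg.sm_floor + cfg.sm_sat) / 2
        assert cfg.g_min < moisture_scaling(cfg, np.array([mid]))[0] < 1.0

    def test_missingness_fraction(self):
        cfg = quiet_cfg(study_hours=20_000, missing_frac=0.07, noise_sd=0.1)
        flux = generate_flux(cfg, generate_temperature(cfg))
        assert 1 - len(flux) / 20_000 == pytest.approx(0.07, abs=0.01)

    def test_subhourly_emission_and_hourly_recovery(self):
        from heatresp import resample_to_hourly

        cfg = quiet_cfg(study_hours=48, subhourly_per_hour=5, noise_sd=0.0)
        flux = generate_flux(cfg, generate_temperature(cfg))
        assert len(flux) == 48 * 5
        hourly = resample_to_hourly(flux)
        assert (hourly.data["n_obs"] == 5).all()
        assert np.allclose(hourly.data["rs"], cfg.rs_ref)

    def test_misaligned_inputs_rejected(self, default_cfg):
        temp = generate_temperature(default_cfg, n_hours=100)
        sm = generate_moisture(default_cfg, generate_temperature(default_cfg, n_hours=50))
        with pytest.raises(ValueError, match="not aligned"):
            generate_flux(default_cfg, temp, sm)

    def test_full_chain_deterministic(self, default_cfg):
        a = generate_site(default_cfg)
        b = generate_site(default_cfg)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.data, y.data)


class TestGroundTruth:
    def test_symmetric_noise_only_generator_gives_half(self):
        cfg = SynthConfig(
            seed=0,
            q10=1.0,
            sm_sat=0.0,  # disables moisture limitation: g = 1 everywhere
            sm_floor=0.01,
            sm_ceiling=0.5,
            noise_sd=0.2,
        )
        gt = ground_truth_exceedance(cfg, "HW", n_hours=100_000)
        assert gt.p == pytest.approx(0.5, abs=3 * gt.se + 0.005)

    def test_q10_orders_heat_conditions_across_seeds(self):
        for seed in range(5):
            cfg = SynthConfig(seed=seed, q10=2.0)
            gt = ground_truth_all_conditions(cfg, n_hours=100_000, seed=seed + 50)
            assert gt["HW"].p > gt["NHW"].p

    def test_standard_error_scales_with_sqrt_n(self):
        cfg = SynthConfig(seed=0)
        small = ground_truth_exceedance(cfg, "NHW", n_hours=100_000, seed=9)
        large = ground_truth_exceedance(cfg, "NHW", n_hours=400_000, seed=9)
        assert small.se / large.se == pytest.approx(2.0, rel=0.2)
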