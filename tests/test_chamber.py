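import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyflux.chamber import (
    QCPolicy,
    RespirationParams,
    SystemConfig,
    compute_Ac_net,
    compute_Ec,
    correct_baseline,
    daily_integrate,
    estimate_respiration,
    filter_records,
    respiration_at,
    volumetric_to_molar_flow,
)
from canopyflux.synthetic import generate_night_respiration


class TestSystemConfig:
    def test_molar_flow_from_volumetric(self):
        # 4.3e-3 m3/s at 25 degC, 101.3 kPa -> ~0.1757 mol/s (ideal gas)
        assert volumetric_to_molar_flow(4.3e-3) == pytest.approx(0.1757, abs=2e-4)

    def test_residence_time_about_70s(self, system_config):
        # 0.3 m3 chamber flushed at 4.3e-3 m3/s
        assert system_config.residence_time == pytest.approx(70.0, abs=1.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SystemConfig(u_e=-1.0)
        with pytest.raises(ValueError):
            SystemConfig(side_transmittance=1.5)


class TestInstantaneousFluxes:
    def test_zero_vapor_gain_gives_zero_ec(self, system_config):
        assert compute_Ec(2.0, 0.0, system_config) == 0.0

    def test_hand_evaluated_transpiration(self, system_config):
        # VP_in 2.00, VP_dif 0.10 kPa, a 0.2 m2, P 101.3 kPa
        assert compute_Ec(2.00, 0.10, system_config) == pytest.approx(0.886, abs=1e-3)

    def test_saturated_record_rejected(self, system_config):
        with pytest.raises(ValueError, match="saturated"):
            compute_Ec(100.0, 2.0, system_config)

    def test_zero_differentials_give_zero_ac(self, system_config):
        assert compute_Ac_net(400.0, 0.0, 0.0, system_config) == 0.0

    def test_hand_evaluated_net_photosynthesis(self, system_config):
        # CO2_dif -10 (drawdown), CO2_out 390, Ec 0.886
        ac = compute_Ac_net(400.0, -10.0, 0.886, system_config)
        assert ac == pytest.approx(8.44, abs=0.01)

    @given(
        vp_in=st.floats(0.5, 3.5),
        vp_dif=st.floats(-0.3, 0.8),
        co2_dif=st.floats(-40.0, 20.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_flux_equations_invert_generator_exactly(self, vp_in, vp_dif, co2_dif):
        """The generator's algebraic inversion round-trips any physical record."""
        from canopyflux.synthetic import simulate_chamber_series

        cfg = SystemConfig()
        ec = compute_Ec(vp_in, vp_dif, cfg)
        ac = compute_Ac_net(400.0, co2_dif, ec, cfg)
        w = pd.DataFrame(
            {
                "time": [0.0], "par": [500.0], "t_air": [25.0], "co2": [400.0],
                "vp": [vp_in], "wind": [1.5], "pressure": [101.3], "sin_beta": [0.5],
            }
        )
        truth = pd.DataFrame({"time": [0.0], "ec": [ec], "ac_net": [ac]})
        log = simulate_chamber_series(w, truth, cfg)
        assert log["vp_dif"].iloc[0] == pytest.approx(vp_dif, abs=1e-10)
        assert log["co2_dif"].iloc[0] == pytest.approx(co2_dif, abs=1e-8)


def _clean_log(n=60, chamber="A"):
    t = np.arange(n) * 720.0
    return pd.DataFrame(
        {
            "time": t,
            "chamber_id": chamber,
            "co2_in": 400.0 - 30.0 * np.sin(np.pi * t / t.max()),
            "co2_dif": -5.0,
            "vp_in": 2.0 + 0.3 * np.sin(np.pi * t / t.max()),
            "vp_dif": 0.05,
            "t_in": 25.0,
            "t_dif": 0.5,
            "w_container": 50.0,
            "radiation": 800.0,
        }
    )


class TestQCFilter:
    def test_clean_series_untouched(self):
        kept, rejected = filter_records(_clean_log())
        assert len(rejected) == 0

    def test_injected_spikes_removed_exactly(self):
        log = _clean_log()
        spike_idx = [10, 20, 30, 40, 50]
        log.loc[spike_idx, "co2_in"] += 80.0  # >> k * MAD of the smooth signal
        kept, rejected = filter_records(log)
        assert sorted(rejected.index) == spike_idx

    def test_all_constant_series_survives_zero_mad(self):
        log = _clean_log()
        log["co2_in"] = 400.0
        log["vp_in"] = 2.0
        kept, rejected = filter_records(log)
        assert len(rejected) == 0

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            filter_records(_clean_log(n=5), QCPolicy(window=7))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_records(_clean_log().iloc[:0])


class TestBaselineCorrection:
    def test_constant_shift_subtracted(self):
        log = _clean_log()
        empty = _clean_log()
        empty["co2_dif"] = 0.5
        empty["vp_dif"] = 0.0
        out = correct_baseline(log, empty)
        assert np.allclose(out["co2_dif"], log["co2_dif"] - 0.5)
        assert np.allclose(out["vp_dif"], log["vp_dif"])

    def test_zero_mean_empty_run_is_identity(self):
        log = _clean_log()
        empty = _clean_log()
        empty["co2_dif"] = 0.0
        empty["vp_dif"] = 0.0
        out = correct_baseline(log, empty)
        assert np.allclose(out["co2_dif"], log["co2_dif"])

    def test_missing_empty_run_warns_and_passes_through(self):
        log = _clean_log(chamber="A")
        empty = _clean_log(chamber="B")
        with pytest.warns(UserWarning, match="no empty run"):
            out = correct_baseline(log, empty)
        assert np.allclose(out["co2_dif"], log["co2_dif"])

    def test_synthetic_leak_recovered(self, system_config):
        # inject a constant soil-leak on the differentials; correction
        # restores the fluxes computed from the clean log
        log = _clean_log()
        leak_co2, leak_vp = 1.2, 0.015
        leaky = log.copy()
        leaky["co2_dif"] += leak_co2
        leaky["vp_dif"] += leak_vp
        empty = log.copy()
        empty["co2_dif"] = leak_co2
        empty["vp_dif"] = leak_vp
        out = correct_baseline(leaky, empty)
        ec_true = compute_Ec(log["vp_in"], log["vp_dif"], system_config)
        ec_corr = compute_Ec(out["vp_in"], out["vp_dif"], system_config)
        assert np.allclose(ec_corr, ec_true, atol=1e-12)


class TestRespiration:
    def test_reference_temperature(self):
        p = RespirationParams(rc25=4.0, erc=9559.0)
        assert respiration_at(25.0, p) == pytest.approx(4.0)

    def test_direct_evaluation(self):
        p = RespirationParams(rc25=4.0, erc=9559.0)
        assert respiration_at(35.0, p) == pytest.approx(4.53, abs=0.01)

    def test_monotone_increasing_for_positive_activation(self):
        p = RespirationParams(rc25=4.0, erc=9559.0)
        t = np.linspace(5.0, 40.0, 50)
        assert (np.diff(respiration_at(t, p)) > 0).all()

    def test_noiseless_fit_recovers_exactly(self):
        t, rc = generate_night_respiration(4.0, 9559.0, t_range=(15.0, 26.0), n=50, seed=1)
        fit = estimate_respiration(t, rc)
        assert fit.rc25 == pytest.approx(4.0, rel=1e-6)
        assert fit.erc == pytest.approx(9559.0, rel=1e-5)

    def test_noisy_fit_within_tolerance(self):
        t, rc = generate_night_respiration(
            4.0, 9559.0, t_range=(15.0, 26.0), n=500, noise=1.0, seed=4
        )
        fit = estimate_respiration(t, rc)
        assert fit.rc25 == pytest.approx(4.0, rel=0.05)
        # activation energy is weakly identified over an 11-K window; the
        # study-scale uncertainty (+-2779 J/mol reported SE) bounds the error
        assert abs(fit.erc - 9559.0) < 2 * 2779.0

    def test_bias_shrinks_with_sample_size(self):
        biases = {}
        for n in (50, 500):
            errs = []
            for rep in range(20):
                t, rc = generate_night_respiration(
                    4.0, 9559.0, t_range=(15.0, 26.0), n=n, noise=1.0, seed=100 + rep
                )
                errs.append(estimate_respiration(t, rc).rc25 - 4.0)
            biases[n] = abs(np.mean(errs))
        assert biases[500] < biases[50] + 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_respiration([20.0, 21.0], [3.0, 3.1])
        with pytest.raises(ValueError, match="spread"):
            estimate_respiration([20.0] * 5, [3.0] * 5)


class TestDailyIntegration:
    def test_constant_flux_closed_form(self):
        # 1 mmol m-2 s-1 held for a full day integrates to 86.4 mol m-2 d-1
        t = np.arange(0, 86401, 720, dtype=float)
        flux = pd.DataFrame(
            {"time": t, "chamber_id": "A", "ec": 1.0, "ac_net": 10.0,
             "rc": 2.0, "ac_gross": 12.0}
        )
        daily = daily_integrate(flux)
        assert len(daily) == 1
        assert daily["ec_daily"].iloc[0] == pytest.approx(86.4)
        assert daily["ac_gross_daily"].iloc[0] == pytest.approx(86400 * 12e-6)
        assert daily["coverage"].iloc[0] == pytest.approx(1.0)

    def test_zero_flux_day(self):
        t = np.arange(0, 86401, 720, dtype=float)
        flux = pd.DataFrame(
            {"time": t, "chamber_id": "A", "ec": 0.0, "ac_net": 0.0,
             "rc": 0.0, "ac_gross": 0.0}
        )
        daily = daily_integrate(flux)
        assert daily["ec_daily"].iloc[0] == 0.0

    def test_long_gap_flags_day(self):
        t = np.concatenate([np.arange(0, 6 * 3600, 720), np.arange(18 * 3600, 86401, 720)])
        flux = pd.DataFrame(
            {"time": t.astype(float), "chamber_id": "A", "ec": 1.0,
             "ac_net": 0.0, "rc": 0.0, "ac_gross": 0.0}
        )
        daily = daily_integrate(flux)
        assert daily["flagged"].iloc[0]
        # the 12-h hole is excluded from the integral, not bridged:
        # ~12 h of 1 mmol m-2 s-1 is ~43.2 mol, not the bridged ~86
        assert daily["ec_daily"].iloc[0] == pytest.approx(43.2, abs=1.5)


def test_gross_at_least_net_whenever_respiring(
    weather_day, canopy, leaf_params, system_config
):
    from canopyflux.chamber import compute_fluxes
    from canopyflux.pipeline import simulate_true_fluxes
    from canopyflux.synthetic import simulate_chamber_series

    truth = simulate_true_fluxes(canopy, weather_day, leaf_params)
    log = simulate_chamber_series(weather_day, truth, system_config)
    flux = compute_fluxes(log, system_config)
    assert (flux["rc"] >= 0).all()
    day = ~flux["night"]
    assert (flux.loc[day, "ac_gross"] >= flux.loc[day, "ac_net"] - 1e-12).all()
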