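import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyflux.canopy import (
    actual_stomatal_resistance,
    beam_extinction,
    canopy_gas_exchange,
    multilayer_gas_exchange,
    partition_sunlit_shaded,
)
from canopyflux.constants import GAMMA_PSY
from canopyflux.leaf import Environment, LeafParams
from canopyflux.structure import CanopyState


class TestBeamExtinction:
    def test_overhead_sun_projects_cos_leaf_angle(self):
        # for leaves at 15 degrees and sun above the leaf plane,
        # kb = cos(alpha)
        assert beam_extinction(15.0, 1.0) == pytest.approx(np.cos(np.deg2rad(15.0)))

    def test_grazing_sun_capped(self):
        assert beam_extinction(15.0, 0.0) == 50.0

    def test_continuous_across_leaf_angle(self):
        sb = np.sin(np.deg2rad(15.0))
        below = beam_extinction(15.0, sb * 0.999)
        above = beam_extinction(15.0, sb * 1.001)
        assert below == pytest.approx(above, rel=0.05)


class TestSunShadePartition:
    def test_empty_canopy(self):
        c = CanopyState(lai=0.0, sln0=1.5, kn=0.3)
        p = partition_sunlit_shaded(c, 0.8, 1000.0, 300.0)
        assert p.lai_sun == 0.0 and p.lai_shade == 0.0
        assert p.i_abs_total == 0.0

    def test_sunlit_lai_matches_layered_integration(self, canopy):
        # LAI_sun = (1 - exp(-kb L))/kb vs 200-layer midpoint sum of exp(-kb x)
        p = partition_sunlit_shaded(canopy, 0.95, 1200.0, 300.0)
        x = (np.arange(200) + 0.5) * canopy.lai / 200
        numeric = np.sum(np.exp(-p.kb * x)) * canopy.lai / 200
        assert p.lai_sun == pytest.approx(numeric, rel=1e-4)

    def test_absorption_bounded_by_incident(self, canopy):
        p = partition_sunlit_shaded(canopy, 0.9, 1500.0, 400.0)
        assert p.i_abs_total <= 1900.0
        assert p.i_abs_sun >= 0 and p.i_abs_shade >= 0

    def test_nitrogen_conserved_exactly(self, canopy):
        p = partition_sunlit_shaded(canopy, 0.8, 1000.0, 300.0)
        assert p.n_sun + p.n_shade == pytest.approx(canopy.nc, abs=1e-10)

    def test_beam_without_sun_rejected(self, canopy):
        with pytest.raises(ValueError):
            partition_sunlit_shaded(canopy, 0.0, 500.0, 100.0)


class TestWaterStressResistance:
    def test_no_stress_limit_returns_potential_resistance(self):
        assert actual_stomatal_resistance(
            ep=5.0, ea=5.0, s=0.145, rbh=25.0, rbw=28.0, rsw_p=100.0
        ) == pytest.approx(100.0)

    def test_half_supply_hand_arithmetic(self):
        # independent hand computation of the closed form at Ea = Ep/2:
        # (Ep-Ea)(s rbh + gamma rbw)/(gamma Ea) + rsw_p Ep/Ea
        ep, ea, s, rbh, rbw, rsw_p = 6.0, 3.0, 0.145, 25.0, 28.0, 100.0
        expected = (ep - ea) * (s * rbh + GAMMA_PSY * rbw) / (GAMMA_PSY * ea) + 200.0
        got = actual_stomatal_resistance(ep, ea, s, rbh, rbw, rsw_p)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.0 * (3.625 + 1.876) / 0.201 + 200.0, rel=1e-3)

    @given(frac=st.floats(0.05, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_at_least_potential_resistance(self, frac):
        got = actual_stomatal_resistance(5.0, 5.0 * frac, 0.18, 20.0, 19.0, 150.0)
        assert got >= 150.0 - 1e-9

    def test_strictly_decreasing_in_available_water(self):
        ea = np.linspace(0.2, 5.0, 40)
        r = actual_stomatal_resistance(5.0, ea, 0.18, 20.0, 19.0, 150.0)
        assert (np.diff(r) < 0).all()

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            actual_stomatal_resistance(5.0, 0.0, 0.18, 20.0, 19.0, 150.0)
        with pytest.raises(ValueError):
            actual_stomatal_resistance(5.0, 6.0, 0.18, 20.0, 19.0, 150.0)


class TestCanopyGasExchange:
    def test_zero_lai_zero_fluxes(self, midday_env, leaf_params):
        c = CanopyState(lai=0.0, sln0=1.5, kn=0.3)
        r = canopy_gas_exchange(c, midday_env, leaf_params)
        assert r.ec == 0.0 and r.ac_gross == 0.0

    def test_dark_canopy_no_gross_photosynthesis(self, canopy, leaf_params):
        env = Environment(par=0.0, t_air=20.0, co2=400.0, vp=1.8, sin_beta=0.0)
        r = canopy_gas_exchange(canopy, env, leaf_params)
        assert r.ac_gross == pytest.approx(0.0, abs=1e-9)
        assert 0.0 <= r.ec < 1.0  # residual cuticular/night conductance only

    def test_water_equal_to_potential_is_identity(self, canopy, midday_env, leaf_params):
        pot = canopy_gas_exchange(canopy, midday_env, leaf_params)
        lim = canopy_gas_exchange(canopy, midday_env, leaf_params, water=pot.ec)
        assert lim.ec == pytest.approx(pot.ec, rel=1e-9)
        assert lim.ac_gross == pytest.approx(pot.ac_gross, rel=1e-9)

    def test_excess_water_does_not_stimulate(self, canopy, midday_env, leaf_params):
        pot = canopy_gas_exchange(canopy, midday_env, leaf_params)
        lim = canopy_gas_exchange(canopy, midday_env, leaf_params, water=2 * pot.ec)
        assert lim.ec == pytest.approx(pot.ec, rel=1e-12)

    def test_actual_converges_to_potential_as_supply_grows(
        self, canopy, midday_env, leaf_params
    ):
        pot = canopy_gas_exchange(canopy, midday_env, leaf_params)
        gaps = []
        for frac in (0.6, 0.8, 0.95, 0.999):
            lim = canopy_gas_exchange(
                canopy, midday_env, leaf_params, water=frac * pot.ec
            )
            gaps.append(pot.ac_gross - lim.ac_gross)
        assert all(g > 0 for g in gaps[:-1])
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 0.01 * pot.ac_gross

    def test_water_limitation_reduces_both_fluxes(self, canopy, midday_env, leaf_params):
        pot = canopy_gas_exchange(canopy, midday_env, leaf_params)
        lim = canopy_gas_exchange(canopy, midday_env, leaf_params, water=0.5 * pot.ec)
        assert lim.ec == pytest.approx(0.5 * pot.ec, rel=1e-6)
        assert lim.ac_gross < pot.ac_gross

    def test_water_limited_efficiency_rises(self, canopy, midday_env, leaf_params):
        # stomatal closure trades proportionally less carbon than water
        pot = canopy_gas_exchange(canopy, midday_env, leaf_params)
        lim = canopy_gas_exchange(canopy, midday_env, leaf_params, water=0.5 * pot.ec)
        assert lim.ac_gross / lim.ec > pot.ac_gross / pot.ec


class TestMultilayerOracle:
    @pytest.mark.parametrize("lai", [0.5, 2.0, 6.0])
    @pytest.mark.parametrize("par", [150.0, 1000.0, 2000.0])
    def test_sun_shade_totals_agree_with_layered_integration(
        self, lai, par, leaf_params
    ):
        """Two-big-leaf totals within 5% of the 200-layer integration of the
        identical leaf model, across canopy sizes and light levels."""
        c = CanopyState(lai=lai, sln0=1.4, kn=0.35)
        env = Environment(par=par, t_air=28.0, co2=400.0, vp=2.0, sin_beta=0.75)
        ss = canopy_gas_exchange(c, env, leaf_params)
        ml = multilayer_gas_exchange(c, env, leaf_params, n_layers=200)
        assert ss.ac_gross == pytest.approx(ml.ac_gross, rel=0.05)
        assert ss.ec == pytest.approx(ml.ec, rel=0.05)

    def test_water_limited_totals_agree(self, canopy, midday_env, leaf_params):
        pot = canopy_gas_exchange(canopy, midday_env, leaf_params)
        water = 0.6 * pot.ec
        ss = canopy_gas_exchange(canopy, midday_env, leaf_params, water=water)
        ml = multilayer_gas_exchange(
            canopy, midday_env, leaf_params, water=water, n_layers=100
        )
        assert ss.ec == pytest.approx(ml.ec, rel=0.05)
        assert ss.ac_gross == pytest.approx(ml.ac_gross, rel=0.07)
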