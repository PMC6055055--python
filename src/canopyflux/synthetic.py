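"""Synthetic weather, chamber-log, canopy-profile and respiration generators.

The study's raw chamber and field records are not deposited, so this module
generates statistically similar data with known ground truth for every
downstream stage:

* `generate_weather` builds a diurnal open-air series: PAR follows solar
  elevation scaled to a configurable midday peak (~2,100 umol m-2 s-1 on
  clear midsummer days), air temperature and vapor pressure are lagged
  sinusoids within the observed daytime ranges (roughly 18-36 degC and
  1.7-2.5 kPa), and CO2 dips at midday within ~360-440 umol mol-1.
* `simulate_chamber_series` inverts the chamber mass-balance equations: given
  true canopy fluxes it writes the logger differentials (VP_dif, CO2_dif)
  that return those fluxes exactly when run through the flux equations,
  plus configurable Gaussian instrument noise on the logged signals.
* `chamber_microclimate` derives in-chamber weather offsets (higher T and VP,
  drawn-down CO2) from the steady-state flow-through mass balance, for
  normalization experiments.
* `generate_canopy_profile` and `generate_night_respiration` produce layered
  canopy measurements and night respiration-temperature samples satisfying
  the exponential extinction and Arrhenius-type response exactly at zero
  noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chamber import SystemConfig, RespirationParams, respiration_at
from .constants import DAY_S, P_STANDARD
from .meteo import saturation_vp, solar_elevation
from .structure import CanopyState, cumulative_nitrogen, relative_light, sln_at_depth

__all__ = [
    "WeatherConfig",
    "SyntheticScenario",
    "generate_weather",
    "simulate_chamber_series",
    "chamber_microclimate",
    "generate_canopy_profile",
    "generate_night_respiration",
]

WEATHER_COLUMNS = ["time", "par", "t_air", "co2", "vp", "wind", "pressure", "sin_beta"]


@dataclass
class WeatherConfig:
    """Shape parameters of the synthetic diurnal weather curves.

    Defaults emulate clear midsummer days at a mid-latitude lowland site:
    temperature rises from ~18 to ~35 degC peaking mid-afternoon, vapor
    pressure and CO2 follow smaller lagged cycles.
    """

    par_peak: float = 2100.0  # umol m-2 s-1 at solar noon
    t_min: float = 18.0  # degC, pre-dawn
    t_max: float = 35.0  # degC, mid-afternoon
    t_peak_time: float = 14.0 * 3600  # s since midnight
    vp_mean: float = 2.1  # kPa
    vp_amplitude: float = 0.4  # kPa
    vp_peak_time: float = 16.0 * 3600
    co2_mean: float = 400.0  # umol mol-1
    co2_amplitude: float = 40.0  # umol mol-1 (midday drawdown)
    wind: float = 1.5  # m s-1
    pressure: float = P_STANDARD


@dataclass
class SyntheticScenario:
    """A full synthetic study condition (site, canopy, water regime)."""

    latitude: float = 45.0
    day_of_year: int = 180
    canopy: CanopyState = field(
        default_factory=lambda: CanopyState(lai=2.2, sln0=1.3, kn=0.35)
    )
    water_fraction: float = 1.0  # fraction of potential transpiration supplied
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    noise_par: float = 0.0
    noise_t: float = 0.0
    noise_vp: float = 0.0
    noise_co2: float = 0.0
    random_seed: int = 0

    def __post_init__(self):
        if not 0 < self.water_fraction <= 1:
            raise ValueError("water_fraction must be in (0, 1]")
        for nm in ("noise_par", "noise_t", "noise_vp", "noise_co2"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


def _diurnal(t, mean, amplitude, peak_time):
    """Sinusoid with a 24-h period peaking at peak_time."""
    return mean + amplitude * np.cos(2.0 * np.pi * (t - peak_time) / DAY_S)


def generate_weather(scenario: SyntheticScenario, cadence_s: int = 720) -> pd.DataFrame:
    """Diurnal open-air weather series at the given cadence.

    PAR is solar-geometry consistent (zero before dawn and after dusk);
    temperature and vapor pressure are smooth lagged sinusoids; vapor
    pressure is capped below saturation. Deterministic given the scenario
    seed.
    """
    if DAY_S % cadence_s != 0:
        raise ValueError("cadence must divide 86400 s")
    w = scenario.weather
    rng = np.random.default_rng(scenario.random_seed)
    t = np.arange(0, DAY_S, cadence_s, dtype=float)

    sin_beta = solar_elevation(scenario.latitude, scenario.day_of_year, t)
    sin_noon = float(
        solar_elevation(scenario.latitude, scenario.day_of_year, DAY_S / 2)
    )
    if sin_noon <= 0:
        raise ValueError("sun never rises for this latitude/day combination")
    par = w.par_peak * sin_beta / sin_noon

    t_air = _diurnal(
        t,
        (w.t_min + w.t_max) / 2.0,
        (w.t_max - w.t_min) / 2.0,
        w.t_peak_time,
    )
    vp = _diurnal(t, w.vp_mean, w.vp_amplitude, w.vp_peak_time)
    # daytime photosynthetic drawdown of ambient CO2, tracking solar elevation
    co2 = w.co2_mean - w.co2_amplitude * np.maximum(sin_beta, 0.0)

    if scenario.noise_par > 0:
        par = np.maximum(par + rng.normal(0, scenario.noise_par, t.size), 0.0)
    if scenario.noise_t > 0:
        t_air = t_air + rng.normal(0, scenario.noise_t, t.size)
    if scenario.noise_vp > 0:
        vp = vp + rng.normal(0, scenario.noise_vp, t.size)
    if scenario.noise_co2 > 0:
        co2 = co2 + rng.normal(0, scenario.noise_co2, t.size)

    vp = np.clip(vp, 0.0, 0.99 * saturation_vp(t_air))
    co2 = np.maximum(co2, 50.0)
    return pd.DataFrame(
        {
            "time": t,
            "par": par,
            "t_air": t_air,
            "co2": co2,
            "vp": vp,
            "wind": np.full(t.size, w.wind),
            "pressure": np.full(t.size, w.pressure),
            "sin_beta": sin_beta,
        }
    )


def simulate_chamber_series(
    weather: pd.DataFrame,
    true_flux: pd.DataFrame,
    cfg: SystemConfig,
    chamber_id: str = "CH1",
    noise_vp_dif: float = 0.0,
    noise_co2_dif: float = 0.0,
    seed: int = 0,
    delta_t: float | np.ndarray = 0.0,
) -> pd.DataFrame:
    """Write logger records whose flux equations return ``true_flux``.

    Inverts the chamber water and CO2 balances for the exit differentials:

        VP_dif  = e a (P - VP_in) / (u_e + e a),        e = Ec / 1000
        CO2_dif = -(Ac_net + 1e-3 Ec CO2_in) / (u_e/a + 1e-3 Ec)

    so that, at zero noise, `compute_Ec`/`compute_Ac_net` round-trip the true
    fluxes to machine precision. Gaussian noise is added on the logged
    differentials (instrument error), never on the derived fluxes.

    ``true_flux`` needs columns time, ec, ac_net on the weather time grid.
    """
    tw = np.asarray(weather["time"], dtype=float)
    tf = np.asarray(true_flux["time"], dtype=float)
    if tw.shape != tf.shape or not np.allclose(tw, tf):
        raise ValueError("weather and true_flux must share a time grid")
    rng = np.random.default_rng(seed)

    ec = np.asarray(true_flux["ec"], dtype=float)
    ac = np.asarray(true_flux["ac_net"], dtype=float)
    vp_in = np.asarray(weather["vp"], dtype=float)
    co2_in = np.asarray(weather["co2"], dtype=float)

    e_mol = ec / 1000.0
    vp_dif = e_mol * cfg.area * (cfg.pressure - vp_in) / (cfg.u_e + e_mol * cfg.area)
    co2_dif = -(ac + 1e-3 * ec * co2_in) / (cfg.u_e / cfg.area + 1e-3 * ec)

    if noise_vp_dif > 0:
        vp_dif = vp_dif + rng.normal(0, noise_vp_dif, vp_dif.size)
    if noise_co2_dif > 0:
        co2_dif = co2_dif + rng.normal(0, noise_co2_dif, co2_dif.size)

    return pd.DataFrame(
        {
            "time": tw,
            "chamber_id": chamber_id,
            "co2_in": co2_in,
            "co2_dif": co2_dif,
            "vp_in": vp_in,
            "vp_dif": vp_dif,
            "t_in": np.asarray(weather["t_air"], dtype=float),
            "t_dif": np.broadcast_to(np.asarray(delta_t, dtype=float), tw.shape).copy(),
            "w_container": np.full(tw.size, 50.0),
            "radiation": np.asarray(weather["par"], dtype=float),
        }
    )


def chamber_microclimate(
    weather: pd.DataFrame,
    flux: pd.DataFrame,
    cfg: SystemConfig,
    radiative_dt_peak: float = 4.0,
    mixing_fraction: float = 0.5,
    apply_par_transmittance: bool = False,
) -> pd.DataFrame:
    """In-chamber weather from the steady-state flow-through mass balance.

    The chamber exit air differs from the intake by the canopy source/sink
    terms: dCO2 = -Ac_net a / u_e (drawdown), dVP from the transpiration
    balance. The canopy itself sits in partially mixed air between inlet and
    outlet, represented by ``mixing_fraction`` (0 = inlet air, 1 = exit air).
    A radiative warming scaled to incident PAR (greenhouse effect of the
    walls, ``radiative_dt_peak`` degC at peak PAR) is added on top.
    ``apply_par_transmittance`` optionally reduces incident PAR by the
    top-wall transmittance; by default the same (externally measured)
    radiation drives both chamber and open-air conditions.
    """
    out = weather.copy()
    ec = np.asarray(flux["ec"], dtype=float)
    ac = np.asarray(flux["ac_net"], dtype=float)
    e_mol = ec / 1000.0
    vp_in = np.asarray(weather["vp"], dtype=float)
    par = np.asarray(weather["par"], dtype=float)

    vp_dif = e_mol * cfg.area * (cfg.pressure - vp_in) / (cfg.u_e + e_mol * cfg.area)
    co2_dif = -(ac + 1e-3 * ec * np.asarray(weather["co2"], dtype=float)) / (
        cfg.u_e / cfg.area + 1e-3 * ec
    )
    dt_rad = radiative_dt_peak * par / max(par.max(), 1.0)

    out["vp"] = np.clip(vp_in + mixing_fraction * vp_dif, 0.0, None)
    out["co2"] = np.maximum(
        np.asarray(weather["co2"]) + mixing_fraction * co2_dif, 50.0
    )
    out["t_air"] = np.asarray(weather["t_air"]) + dt_rad
    if apply_par_transmittance:
        out["par"] = par * cfg.top_transmittance
    out["vp"] = np.minimum(out["vp"], 0.99 * saturation_vp(out["t_air"]))
    return out


def generate_canopy_profile(
    sln0: float,
    kn: float,
    kl: float,
    lai_total: float,
    n_layers: int = 4,
    noise: float = 0.0,
    seed: int = 0,
    height_fracs: tuple = (0.9, 0.75, 0.5, 0.0),
) -> pd.DataFrame:
    """Layered canopy profile satisfying the extinction laws exactly at noise=0.

    Layer boundaries sit at the given fractions of canopy height (defaults
    match ceptometer practice: 90, 75, 50 and 0%); cumulative LAI from the
    top is distributed in proportion to canopy depth. Multiplicative Gaussian
    noise (relative sd ``noise``) perturbs the measured relative light and
    SLN signals.
    """
    if lai_total <= 0:
        raise ValueError("LAI_total must be > 0")
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if kn < 0 or kl <= 0:
        raise ValueError("kn must be >= 0 and kL > 0")
    rng = np.random.default_rng(seed)

    if n_layers != len(height_fracs):
        height_fracs = tuple(np.linspace(0.9, 0.0, n_layers))
    lai_cum = np.array([(1.0 - h) * lai_total for h in height_fracs])
    rel = relative_light(lai_cum, kl)
    sln = sln_at_depth(lai_cum, sln0, kn)
    n_cum = cumulative_nitrogen(lai_cum, sln0, kn)
    if noise > 0:
        rel = np.clip(rel * rng.normal(1.0, noise, rel.size), 1e-6, 1.0)
        sln = np.maximum(sln * rng.normal(1.0, noise, sln.size), 1e-6)
        mid = sln_at_depth((lai_cum + np.concatenate([[0.0], lai_cum[:-1]])) / 2, sln0, kn)
        n_cum = np.cumsum(np.diff(np.concatenate([[0.0], lai_cum])) * mid
                          * rng.normal(1.0, noise, sln.size))
    return pd.DataFrame(
        {
            "height_frac": height_fracs,
            "lai_cum": lai_cum,
            "rel_light": rel,
            "sln": sln,
            "n_cum": n_cum,
        }
    )


def generate_night_respiration(
    rc25: float,
    erc: float,
    t_range: tuple[float, float] = (14.7, 25.7),
    n: int = 100,
    noise: float = 0.0,
    seed: int = 0,
):
    """Night respiration-temperature samples from the Arrhenius-type response.

    Temperatures are drawn uniformly within ``t_range`` (default: the
    observed night chamber range); additive Gaussian noise of sd ``noise``
    perturbs the respiration signal.

    Returns ``(T_air, Rc)`` arrays.
    """
    if rc25 <= 0:
        raise ValueError("Rc25 must be > 0")
    if n < 3:
        raise ValueError("need n >= 3 samples")
    lo, hi = t_range
    if hi <= lo and n > 1:
        raise ValueError("degenerate temperature range: fit would be unidentifiable")
    rng = np.random.default_rng(seed)
    t_air = rng.uniform(lo, hi, n)
    rc = respiration_at(t_air, RespirationParams(rc25=rc25, erc=erc))
    if noise > 0:
        rc = rc + rng.normal(0.0, noise, n)
    return t_air, rc
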