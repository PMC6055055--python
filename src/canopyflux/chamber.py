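"""Whole-canopy chamber fluxes from flow-through gas-exchange logger records.

A canopy enclosed in a flow-through chamber receives a constant molar air flux
u_e (mol s-1); the logger records entrance conditions (CO2_in, VP_in, T_in)
and exit-minus-entrance differentials (CO2_dif, VP_dif, T_dif) every few
minutes, together with container weight and incident radiation. Canopy
transpiration and net photosynthesis per unit ground area follow from the
steady-state mass balance of the chamber:

    Ec     = 1000 * u_e * VP_dif / (a * [P - (VP_in + VP_dif)])      (mmol H2O m-2 s-1)
    Ac_net = -(u_e * CO2_dif / a + 1e-3 * Ec * CO2_out)              (umol CO2 m-2 s-1)

with a the chamber ground area (m2), P the chamber pressure (kPa) and
CO2_out = CO2_in + CO2_dif. Gross photosynthesis adds canopy respiration:
Ac_gross = Ac_net + Rc. Respiration follows an Arrhenius-type temperature
response around 25 degC,

    Rc = Rc25 * exp[ERc * (T - 25) / (298 * R * (T + 273))],

whose parameters (Rc25, ERc) are estimated from night-time records, when
CO2_dif reflects respiration alone.

The module also provides QC spike filtering (rolling median +/- k*MAD),
baseline correction from empty-chamber runs (system leakage / soil
respiration), and trapezoidal daily integration with coverage accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .constants import DAY_S, P_STANDARD, R_GAS, T0_K

__all__ = [
    "SystemConfig",
    "RespirationParams",
    "QCPolicy",
    "volumetric_to_molar_flow",
    "filter_records",
    "correct_baseline",
    "compute_Ec",
    "compute_Ac_net",
    "respiration_at",
    "estimate_respiration",
    "compute_fluxes",
    "daily_integrate",
]

#: Columns of a raw chamber logger table (one row per record).
CHAMBER_COLUMNS = [
    "time",
    "chamber_id",
    "co2_in",
    "co2_dif",
    "vp_in",
    "vp_dif",
    "t_in",
    "t_dif",
    "w_container",
    "radiation",
]


def volumetric_to_molar_flow(q_m3_s: float, T_air: float = 25.0, P: float = P_STANDARD) -> float:
    """Convert a volumetric air flow (m3 s-1) to molar flow (mol s-1), ideal gas."""
    return 1000.0 * P * q_m3_s / (R_GAS * (T_air + T0_K))


@dataclass
class SystemConfig:
    """Geometry and flow configuration of the chamber system.

    Attributes
    ----------
    u_e : molar air flux entering the chamber, mol s-1
    area : chamber ground area, m2
    pressure : chamber air pressure, kPa (standard pressure as proxy; the
        small chamber overpressure is negligible)
    volume : chamber volume, m3 (used only for residence-time diagnostics)
    side_transmittance, top_transmittance : wall optical transmittances
    """

    u_e: float = volumetric_to_molar_flow(4.3e-3)
    area: float = 0.2
    pressure: float = P_STANDARD
    volume: float = 0.3
    side_transmittance: float = 0.87
    top_transmittance: float = 0.93

    def __post_init__(self):
        if self.u_e <= 0 or self.area <= 0:
            raise ValueError("u_e and area must be > 0")
        for t in (self.side_transmittance, self.top_transmittance):
            if not 0 < t <= 1:
                raise ValueError("transmittances must be in (0, 1]")

    @classmethod
    def from_volumetric(cls, q_m3_s: float, T_air: float = 25.0, P: float = P_STANDARD, **kw):
        """Build a config from a volumetric flow converted at (T_air, P)."""
        return cls(u_e=volumetric_to_molar_flow(q_m3_s, T_air, P), pressure=P, **kw)

    @property
    def residence_time(self) -> float:
        """Mean air residence time in the chamber, s (volume / volumetric flow)."""
        q = self.u_e * R_GAS * (25.0 + T0_K) / (1000.0 * self.pressure)
        return self.volume / q


@dataclass
class RespirationParams:
    """Arrhenius-type canopy respiration parameters.

    Rc25 is the respiration rate at 25 degC (umol CO2 m-2 s-1); ERc the
    activation energy (J mol-1).
    """

    rc25: float
    erc: float
    rc25_se: float | None = None
    erc_se: float | None = None

    def __post_init__(self):
        if self.rc25 < 0:
            raise ValueError("Rc25 must be >= 0")


@dataclass
class QCPolicy:
    """Spike rejection: rolling median +/- k*MAD on CO2_in and VP_in."""

    window: int = 7
    k: float = 4.0
    min_abs_tol: float = 1e-9  # guards the all-constant (MAD = 0) case


def filter_records(series: pd.DataFrame, policy: QCPolicy | None = None):
    """Flag and drop records impaired by short-term fluctuations.

    Per chamber, a record is rejected when its CO2_in or VP_in deviates from
    the centered rolling median by more than k times the rolling median
    absolute deviation (MAD). Returns ``(kept, rejected)`` DataFrames.
    """
    policy = policy or QCPolicy()
    if series.empty:
        raise ValueError("chamber series is empty")

    def spike_mask(x: pd.Series) -> pd.Series:
        if policy.window > len(x):
            raise ValueError(
                f"QC window ({policy.window}) longer than series ({len(x)})"
            )

        def is_spike(win: np.ndarray) -> float:
            med = np.median(win)
            mad = np.median(np.abs(win - med))
            dev = abs(win[len(win) // 2] - med)
            return float(dev > policy.k * mad + policy.min_abs_tol)

        out = x.rolling(policy.window, center=True).apply(is_spike, raw=True)
        # partial windows at the series edges are left unflagged
        return out.fillna(0.0).astype(bool)

    bad = pd.Series(False, index=series.index)
    for col in ("co2_in", "vp_in"):
        bad |= series.groupby("chamber_id", group_keys=False)[col].apply(spike_mask)
    return series[~bad].copy(), series[bad].copy()


def correct_baseline(series: pd.DataFrame, empty_runs: pd.DataFrame | None) -> pd.DataFrame:
    """Subtract per-chamber empty-run mean differentials from plant runs.

    Empty-chamber runs (recorded after the plants were cut) capture system
    error from gas leakage and soil respiration; their mean CO2_dif and
    VP_dif per chamber are removed from the plant-run signals. A chamber with
    no empty run gets zero correction and a warning.
    """
    out = series.copy()
    if empty_runs is None or empty_runs.empty:
        warnings.warn("no empty-chamber runs supplied; applying zero baseline correction")
        return out
    base = empty_runs.groupby("chamber_id")[["co2_dif", "vp_dif"]].mean()
    for cid, grp in out.groupby("chamber_id"):
        if cid in base.index:
            out.loc[grp.index, "co2_dif"] -= base.loc[cid, "co2_dif"]
            out.loc[grp.index, "vp_dif"] -= base.loc[cid, "vp_dif"]
        else:
            warnings.warn(f"no empty run for chamber {cid!r}; zero correction applied")
    return out


def compute_Ec(vp_in, vp_dif, cfg: SystemConfig):
    """Canopy transpiration (mmol H2O m-2 s-1) from the chamber water balance."""
    vp_in = np.asarray(vp_in, dtype=float)
    vp_dif = np.asarray(vp_dif, dtype=float)
    denom = cfg.pressure - (vp_in + vp_dif)
    if np.any(denom <= 0):
        raise ValueError("chamber air saturated: P - (VP_in + VP_dif) <= 0")
    return 1000.0 * cfg.u_e * vp_dif / (cfg.area * denom)


def compute_Ac_net(co2_in, co2_dif, Ec, cfg: SystemConfig):
    """Net canopy photosynthesis (umol CO2 m-2 s-1); positive = net uptake.

    The second term corrects for the dilution of exit CO2 by transpired water
    vapor (Ec in mmol m-2 s-1, CO2_out in umol mol-1).
    """
    co2_in = np.asarray(co2_in, dtype=float)
    co2_dif = np.asarray(co2_dif, dtype=float)
    co2_out = co2_in + co2_dif
    if np.any(co2_out <= 0):
        raise ValueError("CO2_out = CO2_in + CO2_dif must be > 0")
    return -(cfg.u_e * co2_dif / cfg.area + 1e-3 * np.asarray(Ec, dtype=float) * co2_out)


def respiration_at(T_air, p: RespirationParams):
    """Canopy respiration (umol CO2 m-2 s-1) at air temperature T_air (degC)."""
    T = np.asarray(T_air, dtype=float)
    return p.rc25 * np.exp(p.erc * (T - 25.0) / (298.0 * R_GAS * (T + 273.0)))


def estimate_respiration(T_air, Rc) -> RespirationParams:
    """Fit (Rc25, ERc) to night-time respiration vs temperature.

    Nonlinear least squares of the Arrhenius-type response. Requires >= 3
    points with nonzero temperature spread.
    """
    T = np.asarray(T_air, dtype=float)
    R = np.asarray(Rc, dtype=float)
    if T.size < 3:
        raise ValueError("need >= 3 night records to fit respiration")
    if np.ptp(T) <= 0:
        raise ValueError("temperature spread is zero; (Rc25, ERc) not identifiable")

    def resid(pars):
        p = RespirationParams(rc25=pars["rc25"].value, erc=pars["erc"].value)
        return respiration_at(T, p) - R

    pars = Parameters()
    pars.add("rc25", value=max(np.mean(R), 0.1), min=0.0)
    pars.add("erc", value=20_000.0, min=-200_000.0, max=500_000.0)
    out = minimize(resid, pars)
    if not out.success:
        raise RuntimeError(f"respiration fit did not converge: {out.message}")
    return RespirationParams(
        rc25=out.params["rc25"].value,
        erc=out.params["erc"].value,
        rc25_se=out.params["rc25"].stderr,
        erc_se=out.params["erc"].stderr,
    )


#: PAR threshold (umol m-2 s-1) below which a record counts as night.
NIGHT_PAR_THRESHOLD = 5.0


def compute_fluxes(
    series: pd.DataFrame,
    cfg: SystemConfig,
    resp: RespirationParams | None = None,
    night_par_threshold: float = NIGHT_PAR_THRESHOLD,
) -> pd.DataFrame:
    """Instantaneous flux series from a QC'd, baseline-corrected chamber log.

    Daytime respiration uses the temperature response evaluated at chamber
    air temperature (T_in + T_dif); night-time respiration is read directly
    from the CO2 balance (Rc = -Ac_net) and gross photosynthesis is zero at
    night by definition. If ``resp`` is None it is fitted from the night
    records of this series.

    Returns a DataFrame with columns time, chamber_id, ec, ac_net, rc,
    ac_gross, night.
    """
    ec = compute_Ec(series["vp_in"], series["vp_dif"], cfg)
    ac_net = compute_Ac_net(series["co2_in"], series["co2_dif"], ec, cfg)
    night = np.asarray(series["radiation"], dtype=float) < night_par_threshold
    t_chamber = np.asarray(series["t_in"], dtype=float) + np.asarray(
        series["t_dif"], dtype=float
    )
    if resp is None:
        resp = estimate_respiration(t_chamber[night], -ac_net[night])
    rc = np.where(night, np.maximum(-ac_net, 0.0), respiration_at(t_chamber, resp))
    ac_gross = np.where(night, 0.0, ac_net + rc)
    return pd.DataFrame(
        {
            "time": series["time"].to_numpy(),
            "chamber_id": series["chamber_id"].to_numpy(),
            "ec": ec,
            "ac_net": ac_net,
            "rc": rc,
            "ac_gross": ac_gross,
            "night": night,
        }
    )


def daily_integrate(
    flux: pd.DataFrame,
    cadence_s: float = 720.0,
    max_gap_steps: int = 3,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Trapezoidal daily integrals of the instantaneous flux series.

    Converts mmol m-2 s-1 (Ec) and umol m-2 s-1 (Ac_gross, Rc) to
    mol m-2 d-1. Days whose largest time gap exceeds ``max_gap_steps`` times
    the cadence, or whose record coverage falls below ``min_coverage``, are
    flagged rather than dropped.

    Returns one row per (chamber_id, day): ec_daily, ac_gross_daily,
    rc_daily, coverage, flagged.
    """
    rows = []
    for cid, grp in flux.groupby("chamber_id"):
        g = grp.sort_values("time")
        t = np.asarray(g["time"], dtype=float)
        if t.size < 2:
            continue
        dt = np.diff(t)
        valid = dt <= max_gap_steps * cadence_s
        mid_day = ((t[:-1] + t[1:]) / 2 // DAY_S).astype(int)

        def interval_sums(y, scale):
            contrib = dt * (y[:-1] + y[1:]) / 2 * scale
            return np.where(valid, contrib, 0.0)

        ec_c = interval_sums(np.asarray(g["ec"], dtype=float), 1e-3)
        ag_c = interval_sums(np.asarray(g["ac_gross"], dtype=float), 1e-6)
        rc_c = interval_sums(np.asarray(g["rc"], dtype=float), 1e-6)
        for day in np.unique(mid_day):
            m = mid_day == day
            coverage = float(np.sum(dt[m & valid]) / DAY_S)
            flagged = bool(np.any(~valid[m]) or coverage < min_coverage)
            rows.append(
                {
                    "chamber_id": cid,
                    "day": int(day),
                    "ec_daily": float(np.sum(ec_c[m])),
                    "ac_gross_daily": float(np.sum(ag_c[m])),
                    "rc_daily": float(np.sum(rc_c[m])),
                    "coverage": min(coverage, 1.0),
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)
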