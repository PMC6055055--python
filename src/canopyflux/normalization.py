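"""Normalization of chamber-measured fluxes to open-air conditions.

Enclosing a canopy changes its micro-environment (warmer, moister, CO2 drawn
down), so chamber-measured transpiration and photosynthesis are not directly
comparable across chambers or to the open air. The validated canopy model
translates them through per-record multiplicative correction factors:

    f_Ec = Ecp_air(sim) / Ecp_chamber(sim)

is the ratio of simulated *potential* canopy transpiration driven by open-air
vs in-chamber weather; the corrected transpiration is Ec_measured * f_Ec.
The photosynthesis factor then compares *water-limited* simulations, feeding
the corrected Ec to the open-air run and the measured Ec to the chamber run:

    f_Ac = Ac_gross_air(sim) / Ac_gross_chamber(sim).

Records where the simulated potential flux is negligible (night) pass
through with factors forced to 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .canopy import canopy_gas_exchange
from .leaf import Environment, LeafParams
from .structure import CanopyState

__all__ = ["compute_f_Ec", "compute_f_Ac", "compute_correction_factors", "normalize_series"]

#: potential flux below which a record counts as night and factors pass as 1
#: (~0.5% of a midday canopy flux; avoids unstable near-zero ratios at the
#: day/night transitions)
NIGHT_FLUX_THRESHOLD = 0.05


def _env_from_row(row) -> Environment:
    return Environment(
        par=float(row["par"]),
        t_air=float(row["t_air"]),
        co2=float(row["co2"]),
        vp=float(row["vp"]),
        sin_beta=float(row["sin_beta"]),
        wind=float(row.get("wind", 1.5)),
        pressure=float(row.get("pressure", 101.3)),
    )


def _check_grids(weather_air: pd.DataFrame, weather_chamber: pd.DataFrame):
    ta = np.asarray(weather_air["time"], dtype=float)
    tc = np.asarray(weather_chamber["time"], dtype=float)
    if ta.shape != tc.shape or not np.allclose(ta, tc):
        raise ValueError("open-air and chamber weather must share a time grid")


def compute_f_Ec(
    canopy: CanopyState,
    weather_air: pd.DataFrame,
    weather_chamber: pd.DataFrame,
    params: LeafParams,
) -> pd.DataFrame:
    """Per-record transpiration correction factor (with night flags).

    Returns a DataFrame with columns time, f_ec, ecp_air, ecp_chamber,
    night.
    """
    _check_grids(weather_air, weather_chamber)
    rows = []
    for (_, ra), (_, rc) in zip(weather_air.iterrows(), weather_chamber.iterrows()):
        ep_air = canopy_gas_exchange(canopy, _env_from_row(ra), params).ec
        ep_ch = canopy_gas_exchange(canopy, _env_from_row(rc), params).ec
        night = ep_ch < NIGHT_FLUX_THRESHOLD or ep_air < NIGHT_FLUX_THRESHOLD
        rows.append(
            {
                "time": float(ra["time"]),
                "f_ec": 1.0 if night else ep_air / ep_ch,
                "ecp_air": ep_air,
                "ecp_chamber": ep_ch,
                "night": night,
            }
        )
    return pd.DataFrame(rows)


def compute_f_Ac(
    canopy: CanopyState,
    ec_corrected,
    ec_measured,
    weather_air: pd.DataFrame,
    weather_chamber: pd.DataFrame,
    params: LeafParams,
) -> pd.DataFrame:
    """Per-record photosynthesis correction factor.

    Both simulations run the water-limited model: the open-air run is driven
    by the corrected transpiration, the chamber run by the measured one.
    Under well-watered conditions the available water approaches the
    potential and the distinction vanishes.
    """
    _check_grids(weather_air, weather_chamber)
    ec_corr = np.asarray(ec_corrected, dtype=float)
    ec_meas = np.asarray(ec_measured, dtype=float)
    if ec_corr.size != len(weather_air) or ec_meas.size != len(weather_air):
        raise ValueError("Ec inputs must align with the weather grids")
    rows = []
    for i, ((_, ra), (_, rc)) in enumerate(
        zip(weather_air.iterrows(), weather_chamber.iterrows())
    ):
        night = ec_meas[i] < NIGHT_FLUX_THRESHOLD
        if night:
            rows.append({"time": float(ra["time"]), "f_ac": 1.0, "night": True})
            continue
        ag_air = canopy_gas_exchange(
            canopy, _env_from_row(ra), params, water=float(ec_corr[i])
        ).ac_gross
        ag_ch = canopy_gas_exchange(
            canopy, _env_from_row(rc), params, water=float(ec_meas[i])
        ).ac_gross
        night = ag_ch < NIGHT_FLUX_THRESHOLD or ag_air < NIGHT_FLUX_THRESHOLD
        rows.append(
            {
                "time": float(ra["time"]),
                "f_ac": 1.0 if night else ag_air / ag_ch,
                "night": night,
            }
        )
    return pd.DataFrame(rows)


def compute_correction_factors(
    canopy: CanopyState,
    flux: pd.DataFrame,
    weather_air: pd.DataFrame,
    weather_chamber: pd.DataFrame,
    params: LeafParams,
) -> pd.DataFrame:
    """Both factors for a measured flux series (columns time, ec, ...).

    The flux series may be thinner than the weather grid (QC-rejected
    records); measured Ec is aligned to the grid by time, interpolating
    across the gaps (those factor values are never applied to a record).
    """
    fec = compute_f_Ec(canopy, weather_air, weather_chamber, params)
    grid = np.asarray(weather_air["time"], dtype=float)
    ec_meas = (
        pd.Series(np.asarray(flux["ec"], dtype=float), index=np.asarray(flux["time"], dtype=float))
        .reindex(np.unique(np.concatenate([grid, np.asarray(flux["time"], dtype=float)])))
        .interpolate(method="index")
        .reindex(grid)
        .fillna(0.0)
        .to_numpy()
    )
    fac = compute_f_Ac(
        canopy, ec_meas * fec["f_ec"].to_numpy(), ec_meas,
        weather_air, weather_chamber, params,
    )
    return pd.DataFrame(
        {
            "time": fec["time"],
            "f_ec": fec["f_ec"],
            "f_ac": fac["f_ac"],
            "night": fec["night"] | fac["night"],
        }
    )


def normalize_series(flux: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Apply per-record factors: Ec *= f_Ec, Ac_gross *= f_Ac.

    Records without a matching factor are flagged and passed through
    unchanged. Sign and zeros of the fluxes are preserved (factors are
    positive).
    """
    out = flux.copy()
    fmap = factors.set_index("time")
    f_ec = fmap["f_ec"].reindex(out["time"]).to_numpy()
    f_ac = fmap["f_ac"].reindex(out["time"]).to_numpy()
    missing = np.isnan(f_ec) | np.isnan(f_ac)
    out["ec"] = out["ec"] * np.where(missing, 1.0, f_ec)
    if "ac_gross" in out:
        out["ac_gross"] = out["ac_gross"] * np.where(missing, 1.0, f_ac)
    out["factor_missing"] = missing
    return out
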