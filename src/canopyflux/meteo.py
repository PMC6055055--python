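"""Micro-meteorological helpers: saturation vapor pressure, solar geometry,
and the direct/diffuse split of incident PAR.

Solar position uses the standard declination / hour-angle formulas; the
diffuse fraction comes from an atmospheric-transmission (clearness-index)
relation of the Spitters type. Both are configurable enough for synthetic
diurnal forcing; no ephemeris-grade accuracy is attempted.
"""

from __future__ import annotations

import numpy as np

from .constants import DAY_S

__all__ = [
    "saturation_vp",
    "svp_slope",
    "solar_declination",
    "solar_elevation",
    "extraterrestrial_par",
    "diffuse_fraction",
    "split_par",
]


def saturation_vp(T_air):
    """Saturation vapor pressure (kPa) at air temperature T_air (degC).

    Tetens formula, adequate between -20 and 50 degC.
    """
    T = np.asarray(T_air, dtype=float)
    return 0.6108 * np.exp(17.27 * T / (T + 237.3))


def svp_slope(T_air):
    """Slope s of the saturation vapor-pressure curve (kPa degC-1)."""
    T = np.asarray(T_air, dtype=float)
    return 4098.0 * saturation_vp(T) / (T + 237.3) ** 2


def solar_declination(day_of_year) -> float:
    """Solar declination (radians) for a day of year (1..365)."""
    doy = np.asarray(day_of_year, dtype=float)
    return -0.4093 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0)


def solar_elevation(latitude_deg, day_of_year, time_s):
    """Sine of the solar elevation angle.

    Parameters
    ----------
    latitude_deg : site latitude, degrees (positive north)
    day_of_year : 1..365
    time_s : seconds since local solar midnight (scalar or array)

    Returns
    -------
    sin_beta : clipped at 0 during night.
    """
    if not -90.0 <= float(latitude_deg) <= 90.0:
        raise ValueError(f"latitude must be in [-90, 90], got {latitude_deg}")
    if not 1 <= int(day_of_year) <= 366:
        raise ValueError(f"day_of_year must be in [1, 366], got {day_of_year}")
    lat = np.deg2rad(float(latitude_deg))
    dec = solar_declination(day_of_year)
    hour_angle = 2.0 * np.pi * (np.asarray(time_s, dtype=float) - DAY_S / 2) / DAY_S
    sin_beta = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(hour_angle)
    return np.clip(sin_beta, 0.0, 1.0)


#: Extraterrestrial PAR photon flux on a plane normal to the beam,
#: umol m-2 s-1 (half of the ~2,600 umol m-2 s-1 total solar constant
#: expressed in photons).
SOLAR_CONSTANT_PAR = 2413.0


def extraterrestrial_par(sin_beta):
    """PAR on a horizontal plane at the top of the atmosphere, umol m-2 s-1."""
    return SOLAR_CONSTANT_PAR * np.asarray(sin_beta, dtype=float)


def diffuse_fraction(par_incident, sin_beta):
    """Diffuse fraction of incident PAR from atmospheric transmission.

    Piecewise clearness-index relation (Spitters-type): overcast skies are
    all-diffuse, very clear skies retain a ~15% diffuse floor.
    """
    par = np.asarray(par_incident, dtype=float)
    sb = np.asarray(sin_beta, dtype=float)
    s0 = extraterrestrial_par(sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(s0 > 0, par / np.where(s0 > 0, s0, 1.0), 0.0)
    tau = np.clip(tau, 0.0, 1.0)
    fdif = np.where(
        tau < 0.22,
        1.0,
        np.where(
            tau < 0.35,
            1.0 - 6.4 * (tau - 0.22) ** 2,
            np.clip(1.47 - 1.66 * tau, 0.15, 1.0),
        ),
    )
    # at night everything is (vacuously) diffuse
    return np.where(sb <= 0.0, 1.0, fdif)


def split_par(par_incident, sin_beta):
    """Split incident PAR into (direct-beam, diffuse) components."""
    par = np.asarray(par_incident, dtype=float)
    fdif = diffuse_fraction(par, sin_beta)
    par_dif = par * fdif
    return par - par_dif, par_dif
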