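"""Canopy structure: light-extinction and nitrogen-profile fitting.

Light attenuates through the canopy following Beer's law on cumulative leaf
area index measured from the top,

    I_i / I_0 = exp(-kL * LAI_i),

and specific leaf nitrogen (SLN, g N m-2 leaf) declines similarly,

    SLN_i = SLN0 * exp(-kn * LAI_i),

so the cumulative leaf-N content down to depth i (g N m-2 ground) is

    N_i = SLN0 * (1 - exp(-kn * LAI_i)) / kn,

with the continuous limit N_i -> SLN0 * LAI_i as kn -> 0.

`fit_kL` and `fit_nitrogen_profile` estimate (kL) and (SLN0, kn) from layered
canopy measurements by ordinary nonlinear least squares on the untransformed
values (log-linearization would distort the error structure at low light/N).
`kn_from_LAI` applies an empirical decaying-exponential relation between the
nitrogen extinction coefficient and canopy size: small canopies keep kn close
to the light extinction coefficient, large canopies relax it toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model, Parameters, minimize

__all__ = [
    "CanopyState",
    "KnLaiRelation",
    "FitResult",
    "cumulative_nitrogen",
    "sln_at_depth",
    "relative_light",
    "fit_kL",
    "fit_nitrogen_profile",
    "fit_sln_profile",
    "kn_from_LAI",
    "fit_kn_lai_relation",
    "normalize_ceptometer",
]

#: Required columns of a layered canopy profile table.
PROFILE_COLUMNS = ["height_frac", "lai_cum", "rel_light", "sln", "n_cum"]


def relative_light(lai_cum, kL):
    """Beer's-law relative light I_i/I_0 at cumulative LAI from the top."""
    return np.exp(-kL * np.asarray(lai_cum, dtype=float))


def sln_at_depth(lai_cum, SLN0, kn):
    """SLN (g N m-2 leaf) at cumulative LAI from the top."""
    return SLN0 * np.exp(-kn * np.asarray(lai_cum, dtype=float))


def cumulative_nitrogen(lai_cum, SLN0, kn):
    """Cumulative canopy leaf N (g N m-2 ground) from top to depth LAI_i.

    Uses the stable form SLN0 * (-expm1(-kn L))/kn, which passes smoothly
    through the uniform-profile limit kn -> 0 (N_i = SLN0 * L).
    """
    L = np.asarray(lai_cum, dtype=float)
    kn = float(kn)
    if abs(kn) < 1e-12:
        return SLN0 * L
    return SLN0 * (-np.expm1(-kn * L)) / kn


@dataclass
class CanopyState:
    """Physiological description of a canopy.

    Attributes
    ----------
    lai : leaf area index, m2 leaf m-2 ground
    sln0 : SLN at the canopy top, g N m-2 leaf
    kn : nitrogen extinction coefficient, m2 m-2
    kl_dif : light extinction coefficient for diffuse light, m2 m-2
    leaf_angle : mean leaf inclination from horizontal, degrees
    """

    lai: float
    sln0: float
    kn: float
    kl_dif: float = 0.96
    leaf_angle: float = 15.0

    def __post_init__(self):
        if self.lai < 0:
            raise ValueError("LAI must be >= 0")
        if self.kl_dif <= 0:
            raise ValueError("kl_dif must be > 0")
        if self.kn < 0:
            raise ValueError("kn must be >= 0")

    @property
    def nc(self) -> float:
        """Total canopy leaf-N content, g N m-2 ground."""
        return float(cumulative_nitrogen(self.lai, self.sln0, self.kn))

    @property
    def sln_mean(self) -> float:
        """Canopy-average SLN, g N m-2 leaf."""
        return self.nc / self.lai if self.lai > 0 else self.sln0


@dataclass
class FitResult:
    """Parameter estimates with standard errors and simple diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float | None]
    rss: float
    ndata: int
    residuals: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, key):
        return self.params[key]


def _profile_arrays(profile: pd.DataFrame, value_col: str):
    lai = np.asarray(profile["lai_cum"], dtype=float)
    y = np.asarray(profile[value_col], dtype=float)
    order = np.argsort(lai)
    return lai[order], y[order]


def fit_kL(profile: pd.DataFrame) -> FitResult:
    """Estimate the light extinction coefficient kL from (LAI_i, I_i/I_0).

    Nonlinear least squares of the Beer's-law profile. Requires at least two
    layers at distinct cumulative LAI and strictly positive light ratios.
    """
    lai, rel = _profile_arrays(profile, "rel_light")
    if np.unique(lai).size < 2:
        raise ValueError("need >= 2 layers with distinct cumulative LAI to fit kL")
    if np.any(rel <= 0):
        raise ValueError("relative light values must be > 0")
    model = Model(lambda x, kL: np.exp(-kL * x), independent_vars=["x"])
    out = model.fit(rel, x=lai, kL=0.5)
    p = out.params["kL"]
    return FitResult(
        params={"kL": p.value},
        stderr={"kL": p.stderr},
        rss=float(np.sum(out.residual**2)),
        ndata=lai.size,
        residuals=out.residual,
    )


def fit_nitrogen_profile(profile: pd.DataFrame) -> FitResult:
    """Estimate (SLN0, kn) from cumulative leaf N vs cumulative LAI.

    Fits N_i = SLN0 (1 - e^{-kn LAI_i}) / kn by nonlinear least squares,
    continuous through kn -> 0 (uniform profile). Requires >= 3 layers with
    strictly increasing cumulative N.
    """
    lai, n_cum = _profile_arrays(profile, "n_cum")
    if lai.size < 3:
        raise ValueError("need >= 3 layers to fit the nitrogen profile")
    if np.any(np.diff(n_cum) <= 0):
        raise ValueError("cumulative N must be strictly increasing with depth")

    def model_fn(pars):
        sln0 = pars["SLN0"].value
        kn = pars["kn"].value
        return cumulative_nitrogen(lai, sln0, kn) - n_cum

    pars = Parameters()
    pars.add("SLN0", value=n_cum[-1] / max(lai[-1], 1e-6), min=1e-6)
    pars.add("kn", value=0.3, min=0.0, max=5.0)
    out = minimize(model_fn, pars)
    if not out.success:
        raise RuntimeError(f"nitrogen-profile fit did not converge: {out.message}")
    res = {n: out.params[n].value for n in ("SLN0", "kn")}
    err = {n: out.params[n].stderr for n in ("SLN0", "kn")}
    return FitResult(
        params=res,
        stderr=err,
        rss=float(np.sum(out.residual**2)),
        ndata=lai.size,
        residuals=out.residual,
    )


def fit_sln_profile(profile: pd.DataFrame) -> FitResult:
    """Alternative estimator fitting SLN_i = SLN0 e^{-kn LAI_i} directly.

    Provided for comparison with `fit_nitrogen_profile`, which operates on the
    cumulative-N form and is the primary estimator.
    """
    lai, sln = _profile_arrays(profile, "sln")
    if lai.size < 3:
        raise ValueError("need >= 3 layers to fit the SLN profile")
    model = Model(
        lambda x, SLN0, kn: SLN0 * np.exp(-kn * x), independent_vars=["x"]
    )
    out = model.fit(sln, x=lai, SLN0=sln[0], kn=0.3)
    return FitResult(
        params={n: out.params[n].value for n in ("SLN0", "kn")},
        stderr={n: out.params[n].stderr for n in ("SLN0", "kn")},
        rss=float(np.sum(out.residual**2)),
        ndata=lai.size,
        residuals=out.residual,
    )


@dataclass
class KnLaiRelation:
    """Empirical kn(LAI) = c * exp(-d * LAI), clipped to (0, kL_dif].

    Small canopies approach kn ~ c (close to the light extinction
    coefficient); kn decays toward zero as canopies grow, but never below a
    tiny positive floor so the cumulative-N integral stays well defined.
    """

    c: float = 0.9
    d: float = 0.5
    kl_dif: float = 0.96

    def __call__(self, lai: float) -> float:
        return kn_from_LAI(lai, self)


def kn_from_LAI(lai, relation: KnLaiRelation):
    """Evaluate the fitted kn-LAI relation at a given LAI."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai <= 0):
        raise ValueError("LAI must be > 0")
    kn = relation.c * np.exp(-relation.d * lai)
    out = np.clip(kn, 1e-9, relation.kl_dif)
    return float(out) if out.ndim == 0 else out


def fit_kn_lai_relation(lai_values, kn_values, kl_dif: float = 0.96) -> KnLaiRelation:
    """Fit the decaying-exponential kn-LAI relation from (LAI, kn) pairs."""
    lai = np.asarray(lai_values, dtype=float)
    kn = np.asarray(kn_values, dtype=float)
    if lai.size < 2:
        raise ValueError("need >= 2 (LAI, kn) pairs")
    model = Model(lambda x, c, d: c * np.exp(-d * x), independent_vars=["x"])
    out = model.fit(kn, x=lai, c=max(kn.max(), 0.1), d=0.5)
    return KnLaiRelation(c=out.params["c"].value, d=out.params["d"].value, kl_dif=kl_dif)


def normalize_ceptometer(rel_light, zenith_angle_deg=None):
    """Normalize below/above-canopy light ratios to a zenith-angle-0 reading.

    Inputs measured at solar zenith angle z are mapped with a simple cosine
    correction, I_norm = I^(cos z); pre-normalized inputs (no zenith angle
    supplied) pass through unchanged.
    """
    rel = np.asarray(rel_light, dtype=float)
    if zenith_angle_deg is None:
        return rel
    z = float(zenith_angle_deg)
    if not 0.0 <= z < 90.0:
        raise ValueError("zenith angle must be in [0, 90) degrees")
    return rel ** np.cos(np.deg2rad(z))
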