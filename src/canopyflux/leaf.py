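"""Leaf-level biochemistry and energy balance for big-leaf canopy fractions.

The photosynthesis model is the Farquhar-von Caemmerer-Berry (FvCB) scheme:
the gross carboxylation rate is the minimum of the Rubisco-limited rate

    Wc = Vcmax (Ci - Gamma*) / (Ci + Kc(1 + O/Ko))

and the electron-transport-limited rate

    Wj = (J/4) (Ci - Gamma*) / (Ci + 2 Gamma*),

with J the non-rectangular-hyperbola response of electron transport to
absorbed PAR. Kinetic constants follow Arrhenius temperature responses
normalized at 25 degC. Photosynthetic capacity scales linearly with leaf
nitrogen above a base SLN: Vcmax25 = chi_v * (SLN - SLN_b).

CO2 supply couples to demand through the series diffusion pathway
(boundary layer, factor 1.37; stomata, factor 1.6 relative to water vapor),
Ci = Ca - A/gc. For a prescribed total conductance each limitation gives a
quadratic in A that is solved analytically; the stomatal conductance itself
follows a Ball-Berry/Leuning-type response to assimilation and leaf-surface
vapor pressure deficit, closed by a damped fixed-point iteration.

Transpiration is Penman-Monteith on the same big-leaf aggregation,

    lambda E = (s Rn + rho_cp D / rbh) / (s + gamma (rbw + rsw) / rbh),

and leaf temperature comes from the linearized energy balance
T_leaf = T_air + (Rn - lambda E) rbh / rho_cp, iterated to convergence
(optionally pinned to air temperature).

All fluxes and conductances in this module are per unit *ground* area of the
canopy fraction being represented; per-leaf boundary-layer resistances are
divided by the fraction's LAI (parallel pathways).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .constants import (
    BOUNDARY_CO2_FACTOR,
    GAMMA_PSY,
    GB_WATER_OVER_HEAT,
    J_PER_UMOL_PAR,
    LAMBDA_MOL,
    O2_MMOL,
    P_STANDARD,
    R_GAS,
    RHO_CP,
    STOMATAL_CO2_FACTOR,
    T0_K,
    molar_density_air,
)
from .meteo import saturation_vp, svp_slope

__all__ = ["LeafParams", "Environment", "BigLeafFlux", "big_leaf_exchange", "arrhenius"]


class LeafParams(BaseModel):
    """Leaf photosynthesis and exchange parameters (configuration input).

    Defaults describe a productive C3 leaf; site- or cultivar-specific values
    should be supplied from configuration.
    """

    #: slope of Vcmax25 vs SLN, umol CO2 (g N)-1 s-1
    chi_vcmax: float = Field(240.0, gt=0)
    #: SLN at which photosynthetic capacity extrapolates to zero, g N m-2
    sln_base: float = Field(0.3, ge=0)
    #: ratio Jmax25 / Vcmax25
    jmax_ratio: float = Field(1.7, gt=0, le=4)
    #: electron transport per absorbed photon at low light, mol e- (mol photon)-1
    kappa2: float = Field(0.40, gt=0, le=0.5)
    #: curvature of the J light response
    theta: float = Field(0.7, gt=0, lt=1)
    #: dark respiration as a fraction of Vcmax25
    rd_frac: float = Field(0.01, ge=0, le=0.1)
    #: leaf PAR scattering coefficient (reflectance + transmittance)
    scattering: float = Field(0.15, gt=0, lt=1)

    # Michaelis constants and CO2 compensation point at 25 degC
    kc25: float = Field(404.9, gt=0)  # umol mol-1
    ko25: float = Field(278.4, gt=0)  # mmol mol-1
    gamma_star25: float = Field(42.75, gt=0)  # umol mol-1

    # activation energies, J mol-1 (warm-adapted Vcmax/Jmax responses)
    e_vcmax: float = Field(90_000.0, gt=0)
    e_jmax: float = Field(50_000.0, gt=0)
    e_kc: float = Field(79_430.0, gt=0)
    e_ko: float = Field(36_380.0, gt=0)
    e_gamma: float = Field(37_830.0, gt=0)
    e_rd: float = Field(46_390.0, gt=0)

    # stomatal coupling (Leuning-type)
    #: residual stomatal conductance to CO2 per unit leaf area, mol m-2 s-1
    g0: float = Field(0.01, ge=1e-4)
    #: dimensionless slope of the gs-A coupling
    a1: float = Field(2.0, gt=0)
    #: VPD sensitivity parameter, kPa (large value = weak humidity closure)
    d0: float = Field(10.0, gt=0)

    #: characteristic leaf width for boundary-layer resistance, m
    leaf_width: float = Field(0.1, gt=0)
    #: net absorbed radiation per unit absorbed PAR energy (accounts for NIR)
    rn_par_factor: float = Field(1.3, gt=0, le=3)
    #: solve the leaf energy balance (else leaf temperature = air temperature)
    energy_balance: bool = True

    @model_validator(mode="after")
    def _physiological(self):
        if self.rd_frac * self.chi_vcmax > 10:
            raise ValueError("implausible dark respiration parameterization")
        return self


@dataclass
class Environment:
    """Instantaneous micro-environment driving the canopy model.

    par in umol photons m-2 s-1 (incident, horizontal); t_air degC; co2
    umol mol-1; vp kPa; wind m s-1; pressure kPa; sin_beta the sine of solar
    elevation (0 at night).
    """

    par: float
    t_air: float
    co2: float
    vp: float
    sin_beta: float
    wind: float = 1.5
    pressure: float = P_STANDARD

    def __post_init__(self):
        if self.co2 <= 0:
            raise ValueError("CO2 must be > 0")
        if self.par < 0:
            raise ValueError("PAR must be >= 0")
        if self.vp < 0:
            raise ValueError("VP must be >= 0")


@dataclass
class BigLeafFlux:
    """Fluxes and resistances of one big-leaf canopy fraction (per ground area)."""

    a_gross: float  # umol CO2 m-2 s-1
    a_net: float  # umol CO2 m-2 s-1
    e: float  # mmol H2O m-2 s-1 (potential, or actual if rsw prescribed)
    rsw: float  # stomatal resistance to water, s m-1
    rbh: float  # boundary-layer resistance to heat, s m-1
    rbw: float  # boundary-layer resistance to water, s m-1
    t_leaf: float  # degC
    ci: float  # umol mol-1
    rn: float  # absorbed net radiation, W m-2


def arrhenius(k25, e_act, t_leaf):
    """Arrhenius temperature scaling normalized to 25 degC."""
    tk = np.asarray(t_leaf, dtype=float) + T0_K
    return k25 * np.exp(e_act * (tk - 298.15) / (298.15 * R_GAS * tk))


def electron_transport(i_abs, jmax, kappa2, theta):
    """J from absorbed PAR: smaller root of the non-rectangular hyperbola."""
    x = kappa2 * i_abs
    b = x + jmax
    disc = np.maximum(b * b - 4.0 * theta * x * jmax, 0.0)
    return (b - np.sqrt(disc)) / (2.0 * theta)


def _net_a_given_gc(x1, x2, gamma_star, ca, rd, gc):
    """Net A for one FvCB limitation with diffusion Ci = Ca - A/gc.

    Solves A = x1 (Ci - Gamma*)/(Ci + x2) - Rd analytically (smaller root of
    the quadratic). gc is the total CO2 conductance, mol m-2 s-1.
    """
    b = gc * (ca + x2) + x1 - rd
    c = gc * (x1 * (ca - gamma_star) - rd * (ca + x2))
    disc = max(b * b - 4.0 * c, 0.0)
    return (b - np.sqrt(disc)) / 2.0


def boundary_resistances(wind, leaf_width, lai_frac):
    """Forced-convection flat-leaf boundary-layer resistances, s m-1.

    Per-leaf rbh = 100 sqrt(w/u); divided by the fraction's LAI to give the
    per-ground-area aggregate (parallel leaves).
    """
    u = max(wind, 0.1)
    rbh_leaf = 100.0 * np.sqrt(leaf_width / u)
    rbh = rbh_leaf / lai_frac
    rbw = rbh / GB_WATER_OVER_HEAT
    return rbh, rbw


def penman_monteith(rn, d_air, s, rbh, rbw, rsw):
    """Penman-Monteith latent-heat flux (W m-2) of a big leaf."""
    num = s * rn + RHO_CP * d_air / rbh
    den = s + GAMMA_PSY * (rbw + rsw) / rbh
    return num / den


_MAX_RSW = 5.0e4  # s m-1; effectively closed stomata


def big_leaf_exchange(
    i_abs: float,
    n_leaf: float,
    lai_frac: float,
    env: Environment,
    params: LeafParams,
    rsw_override: float | None = None,
    t_leaf_override: float | None = None,
) -> BigLeafFlux:
    """Coupled photosynthesis-transpiration solution for one canopy fraction.

    Parameters
    ----------
    i_abs : absorbed PAR of the fraction, umol photons m-2 ground s-1
    n_leaf : leaf N content of the fraction, g N m-2 ground
    lai_frac : leaf area of the fraction, m2 m-2
    env : micro-environment
    params : leaf parameters
    rsw_override : prescribed stomatal resistance to water (s m-1, per ground
        area), as produced by the water-stress formula; disables the
        stomatal model.
    t_leaf_override : prescribed leaf temperature (degC); used to hold the
        potential-mode energy balance when re-evaluating under water stress.
    """
    if lai_frac <= 0:
        return BigLeafFlux(0.0, 0.0, 0.0, _MAX_RSW, _MAX_RSW, _MAX_RSW, env.t_air, env.co2, 0.0)

    vcmax25 = params.chi_vcmax * max(n_leaf - params.sln_base * lai_frac, 0.0)
    jmax25 = params.jmax_ratio * vcmax25
    rd25 = params.rd_frac * vcmax25

    rbh, rbw = boundary_resistances(env.wind, params.leaf_width, lai_frac)
    rn = i_abs * J_PER_UMOL_PAR * params.rn_par_factor
    rho_mol = molar_density_air(env.t_air, env.pressure)
    gb_w_mol = rho_mol / rbw  # boundary conductance to water, mol m-2 ground s-1
    gb_c = gb_w_mol / BOUNDARY_CO2_FACTOR

    t_leaf = env.t_air if t_leaf_override is None else t_leaf_override
    gs_c = params.g0 * lai_frac + 0.05  # starting guess, mol m-2 s-1
    a_net = 0.0
    ci = env.co2
    lam_e = 0.0
    rsw = rsw_override if rsw_override is not None else 100.0

    n_t_iter = 25 if (params.energy_balance and t_leaf_override is None) else 1
    for _ in range(n_t_iter):
        gamma_star = arrhenius(params.gamma_star25, params.e_gamma, t_leaf)
        kc = arrhenius(params.kc25, params.e_kc, t_leaf)
        ko = arrhenius(params.ko25, params.e_ko, t_leaf)
        km = kc * (1.0 + O2_MMOL / ko)
        vcmax = arrhenius(vcmax25, params.e_vcmax, t_leaf)
        jmax = arrhenius(jmax25, params.e_jmax, t_leaf)
        rd = arrhenius(rd25, params.e_rd, t_leaf)
        j = electron_transport(i_abs, jmax, params.kappa2, params.theta)
        d_leaf = max(saturation_vp(t_leaf) - env.vp, 0.01)
        s_slope = float(svp_slope(t_leaf))

        def solve_a(gc):
            a_c = _net_a_given_gc(vcmax, km, gamma_star, env.co2, rd, gc)
            a_j = _net_a_given_gc(j / 4.0, 2.0 * gamma_star, gamma_star, env.co2, rd, gc)
            gross = min(a_c + rd, a_j + rd)
            return gross - rd, gross

        if rsw_override is not None:
            # stomatal conductance to CO2 from the prescribed water resistance
            gs_c = rho_mol / rsw_override / STOMATAL_CO2_FACTOR
            gc = 1.0 / (1.0 / gb_c + 1.0 / gs_c)
            a_net, a_gross = solve_a(gc)
            rsw = rsw_override
        else:
            # damped fixed point on the Leuning-type stomatal response
            for _ in range(60):
                gc = 1.0 / (1.0 / gb_c + 1.0 / gs_c)
                a_net, a_gross = solve_a(gc)
                cs = max(env.co2 - a_net / gb_c, gamma_star + 1.0)
                gs_target = params.g0 * lai_frac + params.a1 * max(a_net, 0.0) / (
                    (cs - gamma_star) * (1.0 + d_leaf / params.d0)
                )
                gs_new = 0.5 * gs_c + 0.5 * gs_target
                if abs(gs_new - gs_c) < 1e-10:
                    gs_c = gs_new
                    break
                gs_c = gs_new
            gc = 1.0 / (1.0 / gb_c + 1.0 / gs_c)
            a_net, a_gross = solve_a(gc)
            gs_w_ms = gs_c * STOMATAL_CO2_FACTOR / rho_mol  # m s-1 per ground
            rsw = 1.0 / gs_w_ms  # finite: gs_c >= g0 * lai_frac

        lam_e = penman_monteith(rn, d_leaf, s_slope, rbh, rbw, rsw)
        lam_e = max(lam_e, 0.0)
        if n_t_iter == 1:
            break
        t_new = env.t_air + (rn - lam_e) * rbh / RHO_CP
        if abs(t_new - t_leaf) < 0.01:
            # keep the temperature the fluxes were actually computed at,
            # so a re-evaluation with t_leaf_override reproduces them exactly
            break
        t_leaf = 0.5 * t_leaf + 0.5 * t_new

    gc = 1.0 / (1.0 / gb_c + 1.0 / gs_c)
    ci = env.co2 - a_net / gc
    e_mmol = lam_e / LAMBDA_MOL * 1000.0
    return BigLeafFlux(
        a_gross=max(a_net + rd, 0.0),
        a_net=a_net,
        e=e_mmol,
        rsw=rsw,
        rbh=rbh,
        rbw=rbw,
        t_leaf=t_leaf,
        ci=ci,
        rn=rn,
    )
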