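"""Physical constants and unit-conversion factors used throughout the package.

Internal unit regime
--------------------
* temperatures in degrees Celsius at interfaces, Kelvin inside Arrhenius terms
* pressures and vapor pressures in kPa
* aerodynamic/stomatal resistances in s m-1; molar conductances in
  mol m-2 s-1, converted with the molar density of air
* water fluxes in mmol H2O m-2 s-1, CO2 fluxes in umol CO2 m-2 s-1
  (instantaneous), mol m-2 d-1 (daily)
"""

#: Universal gas constant, J K-1 mol-1
R_GAS = 8.314

#: Psychrometric constant, kPa degC-1 (fixed by convention)
GAMMA_PSY = 0.067

#: Celsius -> Kelvin offset
T0_K = 273.15

#: Latent heat of vaporization of water, J mol-1 (~44 kJ mol-1 near 25 degC)
LAMBDA_MOL = 44_000.0

#: Volumetric heat capacity of air, J m-3 K-1 (rho_air * c_p at ~20 degC)
RHO_CP = 1_200.0

#: Energy content of PAR, J per umol photons (~0.22 J umol-1; 1 W m-2 ~ 4.55
#: umol m-2 s-1 for sunlight)
J_PER_UMOL_PAR = 0.22

#: Diffusivity ratios relative to water vapor: CO2 through stomata and through
#: the leaf boundary layer.
STOMATAL_CO2_FACTOR = 1.6
BOUNDARY_CO2_FACTOR = 1.37

#: Ratio of boundary-layer conductance for water vapor to that for heat.
GB_WATER_OVER_HEAT = 1.075

#: Ambient O2 mole fraction, mmol mol-1
O2_MMOL = 210.0

#: Seconds in a day
DAY_S = 86_400

#: Standard atmospheric pressure, kPa
P_STANDARD = 101.3


def molar_density_air(T_air: float, P: float = P_STANDARD) -> float:
    """Molar density of air (mol m-3) from the ideal-gas law.

    Parameters
    ----------
    T_air : air temperature, degC
    P : pressure, kPa
    """
    return 1000.0 * P / (R_GAS * (T_air + T0_K))


def resistance_to_molar_conductance(r_s_per_m, T_air, P: float = P_STANDARD):
    """Convert a resistance in s m-1 to a conductance in mol m-2 s-1."""
    import numpy as np

    r = np.asarray(r_s_per_m, dtype=float)
    return molar_density_air(T_air, P) / r
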