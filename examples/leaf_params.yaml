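# Leaf parameter configuration (the shipped defaults, spelled out).
# Capacity-nitrogen scaling
chi_vcmax: 240.0    # Vcmax25 slope vs SLN, umol CO2 (g N)-1 s-1
sln_base: 0.3       # g N m-2 leaf below which capacity extrapolates to zero
jmax_ratio: 1.7     # Jmax25 / Vcmax25
kappa2: 0.40        # e- per absorbed photon at low light
theta: 0.7          # curvature of the J light response
rd_frac: 0.01       # Rd25 as a fraction of Vcmax25
scattering: 0.15    # leaf PAR scattering (reflectance + transmittance)
# Kinetics at 25 degC and activation energies (J mol-1)
kc25: 404.9
ko25: 278.4
gamma_star25: 42.75
e_vcmax: 90000.0
e_jmax: 50000.0
e_kc: 79430.0
e_ko: 36380.0
e_gamma: 37830.0
e_rd: 46390.0
# Stomatal coupling (Leuning-type) and exchange geometry
g0: 0.01            # residual stomatal conductance to CO2, mol m-2 s-1 leaf
a1: 2.0             # gs-A coupling slope
d0: 10.0            # kPa; large value = weak humidity closure
leaf_width: 0.1     # m, boundary-layer length scale
rn_par_factor: 1.3  # net absorbed radiation per unit absorbed PAR energy
energy_balance: true
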