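# Methods

This note documents the models implemented in `canopyflux`, the choices made
where the design was open, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Chamber flux computation

The flow-through chamber is treated as a steady-state, well-flushed volume:
with molar air flux `u_e` entering and the exit−entrance differentials
`VP_dif` (kPa) and `CO2_dif` (µmol mol⁻¹) logged at ~12-min cadence,

    Ec     = 1000 u_e VP_dif / (a [P − (VP_in + VP_dif)])
    Ac,net = −(u_e CO2_dif / a + 1e−3 Ec CO2_out),  CO2_out = CO2_in + CO2_dif.

The second term of `Ac,net` corrects for dilution of the exit CO2 mole
fraction by transpired water vapor. Chamber pressure is fixed at the
101.3 kPa standard value; the few-pascal operating overpressure of such
systems is negligible at this precision. The volumetric→molar flow
conversion uses the ideal gas law; the temperature at which this is done
(ambient 25 °C by default) is a configuration choice exposed on
`SystemConfig.from_volumetric`. With the default geometry (0.3 m³, 4.3·10⁻³
m³ s⁻¹) the mean air residence time is ~70 s, so the steady-state
approximation is good at the 12-min cadence.

**QC.** A record is rejected when its `CO2_in` or `VP_in` deviates from the
centred rolling median (window 7 records) by more than 4 per-window median
absolute deviations. The per-window MAD makes the rule robust both to
smooth diurnal curvature (monotone windows have the centre as their median)
and to the all-constant degenerate case (an absolute tolerance floor guards
MAD = 0).

**Baseline.** Empty-chamber runs (plants cut) capture leakage and residual
soil exchange; their per-chamber mean `CO2_dif`/`VP_dif` is subtracted from
the plant runs. Chambers without an empty run get zero correction and a
warning.

**Respiration.** Night records (incident PAR < 5 µmol m⁻² s⁻¹) give canopy
respiration directly from the CO2 balance; `(Rc25, ERc)` of the
Arrhenius-type response

    Rc = Rc25 exp[ERc (T − 25) / (298 R (T + 273))]

are estimated from them by nonlinear least squares (lmfit). Records are not
binned before fitting. Daytime `Rc` is evaluated from the fit at chamber
air temperature (`T_in + T_dif`); at night gross photosynthesis is zero by
definition and `Rc = −Ac,net` directly. Note the activation energy is
weakly identified over a ~11 K night window: its sampling error at
realistic noise is of the same order as the study-scale uncertainty
(thousands of J mol⁻¹), which the tests respect.

**Daily integration.** Trapezoidal, with interval contributions assigned to
the day containing the interval midpoint. Gaps longer than 3 cadence steps
are excluded from the integral (not bridged) and flag the day, as does
coverage below 50%.

## Canopy structure

Light and nitrogen profiles follow exponential extinction on cumulative
LAI from the canopy top. Fits are ordinary least squares on the
*untransformed* values (not log-linearised), preserving the error structure
where light and N are small. The cumulative-N form
`N_i = SLN0(1−e^(−kn LAI_i))/kn` is the primary nitrogen estimator (it is
the integral the data constrain best); fitting `SLN_i` directly is provided
as an alternative. The implementation passes smoothly through the uniform
profile limit `kn → 0` via `expm1`.

The empirical relation `kn = c·e^(−d·LAI)` (clipped to `(0, kL_dif]`)
captures the observation that small canopies hold their nitrogen profile
close to the light profile (`kn → ~0.9 ≈ kL`) while large canopies relax it
toward uniform. Ceptometer inputs are expected pre-normalised to zenith 0;
a documented cosine correction (`I^cos z`) is applied only when a zenith
angle is supplied.

## Leaf model

FvCB biochemistry with Rubisco- and electron-transport-limited rates;
temperature responses are plain Arrhenius normalised at 25 °C (adequate for
the 15–40 °C range of interest; no deactivation term). Photosynthetic
capacity scales with leaf nitrogen: `Vcmax25 = χ_v (SLN − SLN_b)`,
`Jmax25 = r_J Vcmax25`, `Rd25 = f_Rd Vcmax25`. CO2 supply is the series
diffusion pathway (boundary layer ×1.37, stomata ×1.6 vs water vapor);
given a total conductance each limitation is a quadratic in A solved
analytically, and the Leuning-type stomatal response

    gs = g0·LAI_f + a1·A / [(Cs − Γ*)(1 + Ds/D0)]

is closed by a damped fixed point (60 iterations, 1e-10 tolerance). A
brute-force scalar root-finder over the same equations serves as the test
oracle. Transpiration is Penman–Monteith per canopy fraction,

    λE = (s·Rn + ρcp·D/rbh) / (s + γ(rbw + rsw)/rbh),

with flat-leaf forced-convection boundary resistances `rbh = 100√(w/u)`
per unit leaf area (divided by fraction LAI for the per-ground aggregate)
and `rbw = rbh/1.075`. Net absorbed radiation is approximated as absorbed
PAR energy × 1.3 (NIR allowance, no long-wave term) — a deliberate
simplification configurable via `rn_par_factor`. Leaf temperature solves
the linearised energy balance by damped fixed point (0.01 °C tolerance, 25
iterations), with an option to pin it to air temperature.

**Shipped default parameter set.** Leaf parameters are configuration, not
claims about any particular dataset. The defaults describe a productive,
warm-adapted C3 annual and were chosen once so that the full synthetic
chain produces realistic magnitudes: daily PWUEc of well-watered canopies
4.2–4.7 mmol mol⁻¹ (inside the published 4.0–7.5 envelope for hemp
canopies), midday Ec and Ac,gross peaks of ~9–11 mmol m⁻² s⁻¹ and ~29–40
µmol m⁻² s⁻¹ at LAI 1.8–2.6, and night canopy respiration of 2–4.5
µmol m⁻² s⁻¹. The main levers: `chi_vcmax = 240 µmol g⁻¹N s⁻¹` with
`sln_base = 0.3 g m⁻²` (high leaf capacity), `jmax_ratio = 1.7`,
`kappa2 = 0.40`, `a1 = 2.0` and `d0 = 10 kPa` (a conservative stomatal
slope with weak humidity closure — the weak closure is required for the
canopy to transpire *more* in a warmer chamber, as enclosure experiments
observe), `e_vcmax = 90 kJ mol⁻¹` and `e_jmax = 50 kJ mol⁻¹` (warm-shifted
temperature optimum).

## Sun/shade canopy scaling

Direct-beam extinction `kb` comes from Goudriaan's projection of leaves at
a fixed inclination (default 15°) onto the solar direction (`kb = cos α`
for sun above the leaf plane), capped at 50 near grazing elevation. The
diffuse extinction coefficient is the *fitted* `kL` (it already carries
leaf scattering). Scattered-beam and canopy-reflection terms follow the
standard two-stream forms with leaf scattering σ = 0.15 and a fixed diffuse
canopy reflectance 0.036. Sunlit leaf area is `(1−e^(−kb·LAI))/kb`;
nitrogen is allocated to fractions by integrating `SLN0 e^(−kn x) e^(−kb x)`,
which conserves total canopy N exactly.

Each fraction is integrated over depth with **3-point Gaussian quadrature**
of the coupled leaf model (six leaf-model evaluations per canopy call).
A plain two-big-leaf aggregation was measured at up to ~5% from a 200-layer
reference at LAI 6 (Jensen effects in the light response); the Gauss-3
scheme stays within ~0.5% across LAI 0.5–6 and PAR 100–2000, which the
test suite asserts against the multilayer integrator.

The direct/diffuse split of incident PAR uses a Spitters-type
clearness-index relation on the ratio of measured PAR to its
top-of-atmosphere value.

## Water limitation

Available canopy transpiration (the measured `Ec`) is partitioned across
sunlit/shaded components in proportion to their potential `Ep`. Each
component's stomatal resistance is raised to

    rsw,a = (Ep − Ea)(s·rbh + γ·rbw)/(γ·Ea) + rsw,p·Ep/Ea,

which is algebraically the exact inversion of the Penman–Monteith form
above for flux `Ea` at unchanged available energy — provided `s` is
evaluated at the same leaf temperature the potential-mode solution used.
The implementation therefore holds each component's potential-mode leaf
temperature when re-evaluating photosynthesis under stress; this makes
actual transpiration match the supplied water exactly and the
stress → potential limit continuous to machine precision, at the cost of
ignoring the small warming a water-stressed leaf would experience.
Non-stomatal (biochemical) stress effects are out of scope. `Ep` and `Ea`
are on a per-fraction ground-area basis throughout.

## Chamber-to-open-air normalization

Correction factors are computed per 12-min record and applied
multiplicatively; daily efficiencies integrate the normalised instantaneous
series. `f_Ec` is the ratio of simulated *potential* transpiration under
open-air vs in-chamber weather; `f_Ac` is the ratio of *water-limited*
simulated gross photosynthesis, the open-air run driven by the corrected
`Ec` and the chamber run by the measured `Ec` (under well-watered
conditions the distinction vanishes). Records whose simulated flux falls
below 0.05 mmol m⁻² s⁻¹ (≈0.5% of a midday flux) are treated as night and
pass through with factors of 1 — near dawn the leaf-air vapor gradient is
tiny and the ratio of two near-zero fluxes is legitimately hypersensitive.
Whether in-chamber PAR should be reduced by the wall transmittance before
simulation is exposed as a switch on the synthetic generator (default off:
the same externally measured radiation drives both simulations).

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions for all tests:

* **Weather** — clear-sky diurnal cycles at 45° N, midsummer: PAR follows
  solar elevation scaled to a 2,100 µmol m⁻² s⁻¹ noon peak; temperature
  (18–35 °C) and vapor pressure (~1.7–2.5 kPa) are lagged sinusoids; CO2
  dips ~40 µmol mol⁻¹ at midday. It does **not** emulate cloud fields,
  frontal passages or multi-day autocorrelation; consequently daily flux
  *integrals* run above the published means for the same instantaneous
  peaks (the published days were partly cloudy), and the daily PNUEc of the
  emulated treatments (0.48–0.89 mol d⁻¹ g⁻¹ N) sits above the published
  0.3–0.7 range while the ratio-based PWUEc is unaffected.
* **Chamber logs** — the logger differentials are the *exact algebraic
  inversion* of the flux equations for a prescribed true flux series, so
  noiseless round-trips are machine-precision identities; Gaussian noise is
  added on the logged signals (instrument error), never on derived fluxes.
  Logger noise magnitudes are configurable defaults, not claims about the
  original instruments.
* **Chamber microclimate** — steady-state mass-balance offsets (CO2
  drawdown `−Ac,net a/u_e`, vapor enrichment from the water balance) scaled
  by a mixing fraction (the canopy sits in partially mixed air between
  inlet and outlet; 0.5 by default, 0.25 in the short-campaign-like test
  fixture) plus radiative warming proportional to PAR (≈5 °C at peak in the
  fixture). With these offsets the chamber raises daily potential
  transpiration by ~9%, matching enclosure-effect observations; the
  simulated *photosynthesis* depression (~7% daily) is larger than the
  fraction-of-a-percent effects reported for the original system — the
  shipped leaf set is more temperature- and Ci-sensitive than the original
  parameterisation evidently was — so tests assert the sign and magnitude
  sanity of `f_Ac`, not a published band.
* **Profiles and respiration** — exact exponential/Arrhenius structure plus
  optional noise; temperatures drawn within the observed night range.

Passing tests therefore demonstrate correctness of the computational chain
and statistical behaviour of the estimators under known truth — not
agreement with any particular field dataset.

## Efficiency analysis conventions

Two percent-change conventions are explicit, because published treatment
comparisons mix them: `rel_to_larger` (100·(ref−x)/ref, "lower by …%") and
`rel_to_control` (100·(x−ref)/ref, "increased by …%"). Treatment means are
computed per container-day and then averaged (ratio-of-averages available
behind a flag). `Nc` uses green-leaf canopy nitrogen only.

The forcing analysis re-simulates each treatment with LAI (or top-of-canopy
SLN) forced to a source treatment's value. The profile-shape coefficient
`kn` stays with the treatment under SLN forcing: empirically it tracks
canopy size via the kn–LAI relation, not fertilisation. When nitrogen
treatments differ mainly in canopy size, forced-SLN runs deviate from the
default by a few percent while forced-LAI runs deviate by tens of percent;
the ordering is asserted on the size-driven metrics (Ecp, Ac,gross, PNUEcp)
and on the all-metric aggregate — PWUEcp alone is a ratio of two
LAI-scaling fluxes and is nearly LAI-invariant, so its individual ordering
is not a robust signature.

## Numerical choices and limitations

* Resistances are s m⁻¹ internally; molar conversions use the ideal-gas
  molar density of air at air temperature. γ = 0.067 kPa °C⁻¹ fixed.
* Saturation vapor pressure: Tetens; slope `s` from its analytic
  derivative.
* Solar geometry: standard declination/hour-angle formulas; no ephemeris
  corrections (equation of time, refraction) — irrelevant at the 12-min
  cadence of interest.
* Fits use lmfit (Levenberg–Marquardt); non-convergence raises with the
  solver message rather than returning silently.
* Degenerate inputs (zero LAI, dark canopy, all-constant QC windows,
  saturated chamber air, zero temperature spread) are handled explicitly
  and tested.
* Known limitations: no leaf-angle dynamics, no clumping, no CO2
  enrichment scenarios, no non-stomatal water-stress effects, no
  WPL-density or pressure-broadening corrections beyond the flux equations
  themselves, and no attempt to reproduce any specific historical weather
  record.
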