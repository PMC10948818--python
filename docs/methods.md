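# Methods

This note documents the model equations, the packaged parameter values
and the reasoning behind the genuinely open design choices. Units follow
the package convention: fluxes in gCO₂ m⁻² h⁻¹ internally, gCO₂ m⁻² d⁻¹
for daily aggregates (mean × 24), temperatures in °C, water in mm, PAR in
W m⁻², VPD in kPa.

## Biogenic fluxes

**Canopy GPP.** Leaf-level gross assimilation is a rectangular saturating
light response capped by a multiplicative-limitation ceiling,

    F_GPP(PAR, T_sk, CO₂, U, θ) = A_cap · (1 − exp(−ε·PAR / A_cap)),
    A_cap = A_max · fT(T_sk) · fC(CO₂) · fU(U) · θ,

with a Gaussian temperature optimum `fT = exp(−((T_sk−T_opt)/T_width)²)`,
Michaelis-type CO₂ response `fC = CO₂/(CO₂+K_C)`, and a saturating wind
factor `fU = min(1, U/u_ref)` standing in for the aerodynamic-resistance
role of wind (whether wind should increase or decrease assimilation in an
urban canyon is genuinely ambiguous; the saturating-increase form is a
declared surrogate and is easy to swap out). Leaf skin temperature is
air temperature plus a configurable offset (no leaf energy balance).
Canopy GPP integrates the leaf rate over LAI with Beer–Lambert extinction
(`k_ext` default 0.5), and street-canyon geometry (width w, height h,
roof width r) attenuates the PAR reaching ground vegetation by the
sky-view factor `w/(w+2h)`. The integral is evaluated with fixed-order
Gauss–Legendre quadrature (64 nodes); the integrand is smooth, so the
error is orders of magnitude below the 10⁻⁶ relative tolerance the test
suite enforces against a 10⁴-point brute-force integral. With `k_ext=0`
the integral reduces exactly to `f_V·LAI·F_GPP(PAR_top)`, which is tested.

**Ecosystem respiration.**

    F_R(T_soil, θ, LAI) = R_ref · Q10^((T_soil−T_ref)/10) · g(θ) · (LAI/LAI_ref)^r_lai,
    g(θ) = 1 − (1−θ)^p        (default p = 3).

The moisture response is monotone increasing with g(0)=0 and g(1)=1 —
respiration ceases in fully dry soil and saturates toward field capacity.
The saturating (rather than linear) form is deliberate and load-bearing:
empirically, soil respiration is steeply moisture-limited in dry soil and
nearly moisture-saturated near field capacity, and it is precisely this
asymmetry that lets a wet-climate city respond to irrigation through soil
cooling (temperature-dominant) while a dry-climate city responds through
wetting (soil-water-dominant). With a linear g, the marginal moisture
sensitivity never decays and the moisture term dominates everywhere, for
any physically plausible cooling sensitivity. Whether LAI enters
respiration multiplicatively or through root biomass is not resolvable at
this level of abstraction; the power-law factor with exponent `r_lai`
(default 1) is configurable. Both F_GPP and F_R are plain functions of
their listed arguments, so an alternative land-surface formulation can be
dropped in without touching the scenario machinery.

**Tiling and NEE.** Grid-cell fluxes are the area-weighted sum over
low/medium/high-density tiles (weights may sum to < 1; the remainder is
non-urban and excluded), and `NEE_u = R_u − GPP_u` identically — positive
NEE is a net release to the atmosphere. The identity is enforced
structurally (NEE is always computed as the difference, including for
daily deltas) and tested at every timestep.

## Soil bucket and irrigation

A single-layer volumetric bucket between wilting point (0.10 m³ m⁻³) and
field capacity (0.32 m³ m⁻³) over a 0.40 m depth; normalized moisture
θ spans 88 mm of water. Evapotranspiration is `ET = et_coef·VPD·θ`
(linear moisture stress; `et_coef` 0.16 mm h⁻¹ kPa⁻¹, i.e. a potential
rate of ~0.4 mm h⁻¹ at a 2.4 kPa arid midday VPD). Drainage is a linear
reservoir above field capacity, which the irrigation protocol never
exceeds, so the scheme sheds water only under heavy rain. The water
balance closes exactly by construction (the state is updated in increment
form; a zero-flux hour leaves the state bitwise unchanged) and is
property-tested on random forcing.

Irrigation runs nightly during 21:00–22:00 local time at a configurable
application rate (default 10 mm h⁻¹ — municipal protocols rarely publish
a rate, only the window and the stop rule) and stops the moment soil
water reaches the stop target. The target defaults to field capacity;
the two are kept as separate knobs (`policy.target`) because prescribed
thresholds below field capacity are plausible policy levers.

Soil temperature relaxes (time constant 4 h) toward
`t_offset + t_gain·T_air − cool_soil·ET`: a lagged transform of air
temperature minus evaporative cooling. The 2-m air response to the
irrigation-induced ET difference is `dT₂m = −cool_air·(ET_on − ET_off)`,
fed back into the irrigated arm's leaf temperature. `cool_soil`
(20 °C per mm h⁻¹) ≥ `cool_air` (0.8) is a type invariant, mirroring the
robust observation that irrigation cools soil far more than air; with the
packaged constants a full arid-summer season gives ≈ −0.2 °C air and
−5 °C soil cooling, and the daily-mean hierarchy |dT_soil| ≥ |dT₂m| holds
everywhere by construction. This bucket is a declared stand-in for a
full canyon energy balance: it conserves water exactly and reproduces
directional couplings, not absolute energetics.

## Synthetic forcing

The generator emulates what the flux model needs from a summer in five
climate archetypes: a diurnal air-temperature sinusoid (peak 15:00) with
an AR(1) daily anomaly (σ = 0.6 °C, ρ = 0.5 — scaled so a monthly mean
stays within ~0.5 °C of the archetype mean), a half-sine daylight PAR
curve (06–20 h; no solar-geometry model), a VPD cycle tied to the
daylight curve, Bernoulli convective rain placed in afternoon hours
(12–18 h) with exponentially distributed depth and a cloud/VPD reduction
on rain days, weak wind noise, and a diurnal CO₂ cycle (nocturnal
maximum). Heatwave windows add a constant temperature offset plus a
proportional VPD excursion (0.08 kPa per °C), which is what makes the
cooling benefit of irrigation larger inside heatwaves. All randomness
flows from one integer seed; identical inputs are bitwise reproducible.

What it does *not* emulate: synoptic fronts, persistent droughts,
humidity–rain autocorrelation, inter-annual variability, and any spatial
structure. Passing tests therefore demonstrate that the *mechanism*
(moisture vs temperature control of the respiration response) is
recovered under clean summer forcing — not that city-specific magnitudes
from coupled atmospheric simulations are reproduced. Absolute flux
magnitudes carry the uncertainty of the vegetation parameters.

## Archetype calibration

The packaged archetype constants were set once, from the mechanism
analysis, so that the climate contrast expresses itself: the arid
archetype (rare rain, VPD 2.4 kPa, climatological θ₀ = 0.2, sparse xeric
vegetation LAI 1.6 / f_V 0.25 on the low-density tile) wets up from near
wilting point under irrigation and is soil-water-dominant with rising
respiration; the humid-continental archetype (rain every other day,
VPD 1.1 kPa, θ₀ = 0.9, LAI 3.5 / f_V 0.50) sits near field capacity,
its moisture term collapses under the saturating g(θ), and the cooling
term wins — respiration falls and irrigation is a co-benefit. Vegetation
abundance also scales with development density (×1.0/0.7/0.4 for
low/medium/high tiles, with taller canyons at higher density). These
presets live in `scenario.default_surface` and are plain data, not
hard-coded behavior.

## Scenario diagnostics

Paired runs share one forcing series and differ only in
`IrrigationPolicy.enabled`. Deltas are daily means (season mean = mean
of daily means, unweighted). The dR decomposition re-evaluates the
aggregated respiration function hourly on mixed trajectories —
`F_R(T_base, θ_irr) − F_R(T_base, θ_base)` for the moisture term and the
converse for temperature — rather than using analytic partials, so it is
exact for any pluggable F_R; the interaction is reported as an explicit
residual and the three terms sum to dR at machine precision. Dominance
classification compares term magnitudes with an additive tie band
(`tol`, default 0.01 gCO₂ m⁻² d⁻¹).

The five pathway categories operationalize a verbal taxonomy; the
thresholds are this package's choices, exposed in config: `eps`
(neutrality half-width, 0.05 gCO₂ m⁻² d⁻¹) and `share_lo` (0.25) — a
tradeoff with a GPP offset share below `share_lo`, or any tradeoff with
falling GPP, counts as strong. The classifier is a total function on the
(dGPP, dR) plane, property-tested on a grid.

## Accounting

Molar conversions use 44.01 g mol⁻¹ for CO₂ (required to reproduce the
standard 6.5 gCO₂ m⁻² d⁻¹ ↔ 1.7 µmol m⁻² s⁻¹ pairing). The BEV chain
multiplies a dNEE by the irrigated fraction of urban area (default 0.15;
published usage estimates run up to 0.20, and the CLI help says so), the
urban area (2.7×10¹¹ m² for the lower 48 states) and the season length
(123 days for May 1 – Aug 31), and divides by the per-vehicle annual
saving of a gasoline-to-BEV swap (15.7 − 3.5 = 12.2 kgCO₂ d⁻¹ × 365 d =
4.45 t yr⁻¹). Note that 12.2 × 365 is 4.453 t, which reference material
customarily rounds to 4.4; the package reports the exact value. Raw
values are always retained; report rounding is 2 significant figures.

## Numerical choices and degenerate inputs

- Quadrature: Gauss–Legendre 64 on [0, LAI]; `A_cap → 0` handled by the
  exact limit `F_GPP → 0` (no division by zero).
- Time: local-time, hour-resolution, interval-start labels, no DST
  (summer seasons only). Misaligned axes and NaN forcing raise with the
  offending timestamps.
- The soil step limits ET to the water available above wilting point and
  sheds super-capacity storage to drainage; both clampings are flagged in
  the diagnostics, never silent.
- ET = 0 whenever VPD = 0 or θ = 0; irrigation on a full bucket adds 0.
- `gpp_share` is NaN (reported as missing, not an exception) when no
  improving component exists.

## Known limitations

Single soil layer, no runoff routing or snow; no anthropogenic CO₂
sectors (building/vehicular/human); no CO₂ fertilization dynamics or
species traits; air-temperature feedback on GPP is first-order only; the
wind limitation in F_GPP is a guess at the aerodynamic-resistance role;
problem sizes in the test-suite and acceptance runs are single-cell
30–123-day seasons, chosen as the smallest scale at which the seasonal
mechanism statistics are stable.
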