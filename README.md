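# urbiflux

Urban lawns and parks are routinely irrigated to fight the urban heat
island, and the cooling works: wetter soil evaporates more, lowering soil
and 2-m air temperature. But the same water changes the carbon balance of
urban green spaces. Moister soil speeds up both photosynthesis and
microbial/root respiration, while cooler soil slows respiration down —
two opposing levers on the net CO₂ exchange. Depending on which lever
wins, irrigation is a heat–carbon *co-benefit* (cooling **and** extra
sequestration) or a *tradeoff* (cooling at the price of extra CO₂
release). `urbiflux` is a desk-scale simulator of exactly this coupling,
for researchers and practitioners who want to explore the mechanism
without running a mesoscale atmospheric model.

## The model

Hourly urban biogenic CO₂ fluxes follow a tiled single-layer canopy
formulation:

```
GPP_u = f_V ∫₀^LAI F_GPP(PAR·e^(−k·L), T_sk, [CO₂], U, θ) dL      (canopy uptake)
R_u   = f_s · F_R(T_soil, θ, LAI)                                  (ecosystem respiration)
X_u   = f_u,L·X_u,L + f_u,M·X_u,M + f_u,H·X_u,H                    (density tiling)
NEE_u = R_u − GPP_u                                                (positive = net release)
```

`F_GPP` is a saturating light response capped by a gross-assimilation
ceiling with multiplicative temperature, CO₂, wind and soil-moisture
limitations; `F_R` is a Q10 temperature response times a saturating soil
moisture factor `g(θ) = 1 − (1−θ)^p` and an LAI scaling. θ is soil
moisture normalized between wilting point and field capacity. Both
functions are plain pluggable functions of their listed arguments.

The drivers come from a seeded synthetic-forcing generator (five summer
climate archetypes, arid → marine, with optional heatwave windows) and a
single-layer soil bucket with the standard municipal irrigation protocol:
water is applied nightly at 21:00–22:00 local time and stops as soon as
soil water reaches field capacity, so the scheme never produces runoff.
Evapotranspiration `ET = et_coef·VPD·θ` cools the soil
(`−cool_soil·ET`) and, more weakly, the 2-m air (`−cool_air·ΔET`).

A *scenario* runs the pipeline twice over the same forcing — irrigation
off vs on — and diagnoses the daily-mean deltas (dT₂m, dT_soil, dSWC,
dGPP_u, dR_u, dNEE_u). The respiration change is decomposed by
counterfactual re-evaluation into a soil-moisture term (∂R_u/∂SWC) and a
soil-temperature term (∂R_u/∂T_soil) to label each run
soil-water-dominant or temperature-dominant, and the joint (dGPP_u,
dR_u) outcome is classified into five pathways from strong co-benefit to
strong tradeoff. An accounting module converts a dNEE_u into tons of CO₂
and the equivalent number of gasoline-to-BEV vehicle replacements.

## Worked example

```python
import datetime as dt
import urbiflux as uf
from urbiflux.scenario import run_archetype_scenario, classify_run, decompose_dR

run = run_archetype_scenario("arid", dt.date(2015, 5, 1), 30, seed=5)
print(run.delta.season.round(3))
print(decompose_dR(run))
print(classify_run(run))
```

prints

```
dT2m     -0.195
dTsoil   -4.856
dSWC      0.742
dGPP      0.907
dR        3.765
dNEE      2.858
DRDecomposition(moisture=6.06..., temperature=-0.33..., residual=-1.97..., dR=3.76...)
PathwayClass(category='strong_tradeoff', dominance='soil_water_dominant', gpp_share=1.0)
```

Irrigating the arid-archetype city for a month cools the air by 0.20 °C
and the soil by 4.9 °C, but nearly saturates the previously dry soil
(dSWC +0.74). The moisture term of the respiration decomposition (+6.06
gCO₂ m⁻² d⁻¹) dwarfs the cooling term (−0.33), so respiration rises by
3.8 gCO₂ m⁻² d⁻¹ — far more than the GPP gain of 0.9 — and the city lands
on the strong-tradeoff pathway: 2.9 gCO₂ m⁻² d⁻¹ of extra net release.
Running the same experiment with `"humid_continental"` flips the outcome:
the soil is already near field capacity, the moisture term collapses, the
cooling term wins (temperature-dominant), and irrigation yields a
co-benefit (dR_u < 0, dNEE_u < 0).

The same pipeline is available from the shell:

```sh
urbiflux scenario --archetype arid --seed 5 --n-days 30 --out runs/arid
urbiflux report --dnee 0.22          # carbon equivalence of an NEE change
urbiflux classify --dgpp 0.3 --dr -0.4
```

Every run writes its trajectories (CSV/NetCDF), a daily delta table, a
classification JSON and a provenance record (config hash, seed, version).

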