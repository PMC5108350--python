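# grassflux

A process-based, field-scale, daily-time-step simulator of managed
grassland soil–plant–livestock systems, written for agroecosystem
modellers who want a fully testable pipeline: soil water and heat
transport, coupled soil carbon–nitrogen cycling, sward growth, grazing
returns, climate-ensemble scenario construction, and the model-evaluation
statistics used to validate such simulators against field data. Every
input the pipeline needs can be generated synthetically, so the whole
system runs — and is tested — without any site data or downloads.

## What it models

**Soil water.** Vertical flow in a layered column by the Richards
equation, ∂θ/∂t = ∂/∂z[K(h)(∂h/∂z − 1)] − S, with van Genuchten–Mualem
retention and conductivity, ponded-Darcy infiltration (excess → surface
runoff), a unit-gradient drained lower boundary (flow to the field-drain
network), and FAO-56 Penman–Monteith reference evapotranspiration
partitioned by Beer's-law canopy cover. Soil temperature follows Fourier
conduction.

**Soil C and N.** Four organic pools per layer (fresh OM, litter, humus,
dissolved OM) plus ammonium and nitrate. First-order decomposition with
Q10 temperature and water-filled-pore-space (WFPS) moisture responses;
C:N-balanced mineralization–immobilization; Michaelis–Menten
nitrification with a fixed N₂O fraction; denitrification above a WFPS
threshold with the N₂O:N₂ split shifting to N₂ near saturation; advective
leaching and runoff losses of NO₃, DOC, DON and a mobile NH₄ fraction.

**Plants.** A development index DI = Σ max(0, T̄ − T_b)/τ accumulated
from sowing or the last cut keys the partitioning of photosynthate among
leaf, stem and root. GPP = RUE · Rs(1 − e^(−k·LAI)) · f(T) · min(W, N) ·
f(CO₂); maintenance + growth respiration; N uptake by root-weighted
mineral-N availability; legume fixation fills the residual N deficit;
roots extend with thermal time (deep-rooting cultivars are a parameter
set, not new code); cutting removes herbage above stubble and resets DI.

**Livestock.** Grazing is event-based intake (bites/day × bite mass) and
excreta returns per animal; urine and faecal N reach the soil after fixed
ammonia-volatilization reductions (0.600 of urine N, 0.086 of faecal N),
with the urine NH₄/DON split obeying
NH₄ + DON = volume × [N] × (1 − NH₃ fraction).

**Climate scenarios.** A weather-generator ensemble is collapsed to one
series: every element except precipitation is the cross-member daily
mean; precipitation is rebuilt from cross-member mean monthly totals and
rain-day counts, distributed randomly within each month (seeded).

**Evaluation statistics.** The Smith-style suite — r, RMSE (% of observed
mean), modelling efficiency EF, the scatter-ratio R², relative error RE,
mean deviation MD, maximum error ME, with 95 %-confidence variants when
replicate SEs exist — plus one-way ANOVA with LSD thresholds.

## Worked example

```
python examples/run_simulation.py
```

prints, for the fertilized permanent-pasture fixture (year 2):

```
year 2002 annual budget for fixture-sustainable_intensification
  water  (mm)      precip  1027.6  ET  478.9  runoff   0.0  drainage  568.9
  carbon (kg C/ha) GPP    13781  plant resp    6236  soil resp   2603  offtake   5280
  nitrogen (kg N/ha) fertilizer   180  excreta 100.0  leached   9.2  gaseous 169.1
  daily water closure residual never exceeded 3.6e-15 mm
```

Rain on this drained clay grassland leaves mostly as evapotranspiration
and drain flow; the sward fixes ~13.8 t C ha⁻¹ yr⁻¹ of which roughly half
is respired back and ~5.3 t C ha⁻¹ leaves as cut/grazed herbage; N losses
are dominated by gaseous terms (volatilized excreta N plus N₂O + N₂).
The closure line shows the daily water ledger balancing to float
precision — every simulated day is checked for water, C and N closure and
the run aborts if any ledger fails.

Other narrative scripts in `examples/`: `build_scenario.py` (ensemble →
scenario with the conservation check), `compare_treatments.py` (fertilized
vs grass/clover vs deep-rooting reseed under identical forcing),
`evaluate_model_fit.py` (simulate → observe → score), and
`livestock_returns.py` (intake and excreta arithmetic). A YAML-driven CLI
wraps the same library calls:

```
grassflux simulate --config examples/run_config.yaml --out run/
grassflux evaluate --csv pairs.csv
grassflux synth ensemble --members 20 --out members/
grassflux build-scenario --members members/ --seed 1 --out scenario.csv
```

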