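# Methods

This note documents the model equations, the numerical choices, the
synthetic-data generator's scope, and the design decisions taken where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Soil water

The column is a 1-D stack of layers with nodes at layer centres. Water
content follows the mixed (θ–h) form of the Richards equation with
backward-Euler time stepping:

    dz_i (θ_i^{n+1} − θ_i^n)/Δt = q_{i−1/2} − q_{i+1/2} − S_i,
    q_{i+1/2} = K_{i+1/2} ((h_i − h_{i+1})/Δz_{i+1/2} + 1)   (z positive down)

with arithmetic-mean internodal conductivity. Retention and conductivity
are van Genuchten–Mualem; the residual water content is set to θ_wp/2,
which therefore also serves as the hard numerical floor on θ.

Boundary conditions. The surface receives throughfall at a supply rate
capped by a ponded-Darcy infiltration capacity K_s(1 − h₁/(dz₁/2)); the
excess is surface runoff (both infiltration- and saturation-excess emerge
from this single rule). The lower boundary is unit-gradient free drainage.
When the field is drained — the default for the clay fixtures — the
bottom of the profile (0.85 m for the shipped 4-layer column) coincides
with drain depth and the outflow is booked as field drainage rather than
deep percolation; the flume observable is runoff + drainage. This is the
field-lumped abstraction of a drained clay grassland; no drain-spacing
geometry is modelled.

Numerics. Full Newton iteration on matric potential with analytic ∂K/∂h
in the Jacobian, a residual-norm backtracking line search, and two
safeguards for the saturation kink at h = 0 where the storage Jacobian is
discontinuous: iterates never jump across h = 0 in a single move (they
land on the kink), and a ponded branch with a small specific storage
(10⁻⁴ m⁻¹) keeps the system regular when layers saturate. For n < 2 the
Mualem conductivity has a vertical tangent at saturation, which defeats
any Newton-type scheme on wet clay; K(Se) is therefore continued linearly
from Se = 0.99 to K_s (a standard regularization, applied identically in
the public `hydraulic_conductivity` and inside the solver, so oracle
comparisons see the same constitutive law). Convergence requires the mass
residual below 10⁻⁹ m d⁻¹ per layer (≈10⁻⁶ mm d⁻¹) or a full-step update
below 10⁻⁸ m; failures halve the sub-step adaptively (minimum Δt/256),
and a stalled Newton hands the sub-step to a trust-region root finder
before giving up. Days with rainfall are integrated with quarter-day
sub-steps because infiltration fronts carry the dominant temporal error;
this brings the daily implicit solution within 1 % per layer of a
fine-time-step (2 × 10⁻⁵ d) explicit integration of the same equations on
the packaged 3-layer column, which the test suite checks.

Evapotranspiration is FAO-56 Penman–Monteith reference ET₀ (latitude
50.77° N, elevation 180 m by default), partitioned by Beer's-law cover
with extinction 0.5; per-layer extraction is potential transpiration ×
root fraction × a linear availability factor between wilting point and
field capacity, deliberately not renormalized — a sparse or dry root zone
extracts less, which is what makes deep-rooting cultivars
hydrologically different. Soil evaporation draws on the top layer.

## Soil heat

Fourier conduction, backward Euler, Dirichlet surface boundary at the
daily mean air temperature, insulated bottom. Default thermal properties
(λ = 1.2 W m⁻¹ K⁻¹, C_v = 2.5 MJ m⁻³ K⁻¹) give a damping depth of ≈2.2 m
for the annual cycle; the discretized solution reproduces the analytic
amplitude decay e^{−z/d} within 5 % at 0.2–1 m on a fine test column.
Thermal parameters are constants per layer (no moisture coupling).

## Soil carbon and nitrogen

Each layer holds fresh OM, litter, humus and dissolved OM (C and N each),
NH₄ and NO₃. Decomposition of pool p is first-order,
ΔC = C(1 − e^{−k_p f_T f_W Δt}), with the retained fraction
(microbial efficiency e = 0.45) routed to humus (fresh OM, litter, DOM)
or to DOM (humus), and the remainder respired. Source-pool N is released
as gross mineralization; the retained C demands N at the receiver C:N
(10), drawn from NH₄ then NO₃; if mineral N cannot cover the net demand,
decomposition is scaled back proportionally so pools never go negative.
Rate constants (humus 8 × 10⁻⁵, litter 0.01, fresh OM 0.05, DOM
0.1 d⁻¹) are order-of-magnitude values from the process-model literature
and are calibration targets, not measurements.

f_T is Q10 = 2 referenced to 20 °C (capped at 3); f_W is piecewise linear
in WFPS with optimum 0.6, falling to 0.2 at saturation. Nitrification is
Michaelis–Menten in NH₄ (V_max 20 kg N ha⁻¹ d⁻¹, K_m 5 kg N ha⁻¹) with an
aeration factor declining linearly above WFPS 0.6 and a fixed 2 % N₂O
fraction. Denitrification activates above WFPS 0.62, Michaelis–Menten in
NO₃, limited by the same step's heterotrophic CO₂ (half-saturation
5 kg C ha⁻¹ d⁻¹) as the C-availability proxy; the N₂O share of products
declines linearly to zero at WFPS 1, so products always sum to the NO₃
consumed. Solute transport is a top-down mixing-cell advection with the
day's inter-layer flows (reconstructed from the water step by
continuity); mobile fractions are 1 for NO₃/DOC/DON and 0.10 for NH₄
(adsorption proxy); runoff interacts with the top 5 cm. Atmospheric
deposition is a constant 15 kg N ha⁻¹ yr⁻¹ spread daily.

## Plants

The development index advances by max(0, T̄ − T_b)/τ with τ = 1000 °C·d —
calibrated so a full seasonal cycle of the synthetic climate (≈280
growing days) traverses the breakpoint range; τ is a fixture constant,
not an authoritative value. Partition fractions (leaf/stem/root) are
interpolated between DI breakpoints and always sum to 1. Establishment
and regrowth share the same coefficients by default (an optional
root-biased establishment set is a documented extension point, shipped
off) — consequently early post-reseeding growth is generous, a known
behaviour of this coefficient-sharing structure. GPP uses
radiation-use efficiency (ryegrass 1.5 g C MJ⁻¹) with a trapezoidal
temperature response (optimum 18–25 °C), Beer's-law interception, the
minimum of water and N stress, and a logarithmic CO₂ response equal to 1
at the reference 695 mg CO₂ m⁻³ (all scenarios run at this fixed
concentration). Maintenance respiration (1 % of plant C per day at 20 °C,
Q10 = 2) is capped at the day's GPP — no reserve remobilization — so the
annual C ledger keeps respiration below GPP structurally. Growth
respiration is 25 % of post-maintenance assimilate. LAI = SLA × leaf DM
with SLA 0.02 ha kg⁻¹; DM ↔ C conversions use a C fraction of 0.45
everywhere. N uptake per layer is 0.5 × mineral N × root fraction, scaled
to demand (deficit to target organ N concentrations); legume fixation
fills the remaining deficit up to 2 kg N ha⁻¹ d⁻¹ (white clover), so
fixation is automatically zero whenever uptake meets demand and declines
as mineral N rises. Roots extend with thermal time to a species maximum
(ryegrass 0.4 m, Festulolium-type 1.0 m) with an exponential density
profile truncated at root depth. Leaf and root turnover (0.003 and
0.002 d⁻¹) feed the litter and fresh-OM pools. Cutting removes
above-ground mass above 1000 kg DM ha⁻¹ stubble and resets DI; grazing
removes intake demand capped at the same stubble.

## Livestock

Shipped parameter sets: adult beef cattle (600 kg) and ewes (75 kg), with
intake 25 220 × 0.775 g and 33 480 × 0.087 g DM d⁻¹ respectively, and
event-based urine/faeces N returns reduced at source by fixed
NH₃-volatilization fractions (0.600 urine, 0.086 faeces), temperature
independence deliberate. The urine NH₄/DON split is stored data and must
satisfy NH₄ + DON = volume × [N] × (1 − NH₃ fraction) at load (beef:
2.2 × 17 × 0.4 − 11.07 = 3.89 g DON per event; sheep: 0.550 g). The beef
faecal table is internally inconsistent (235 g DM × 0.025 g N g⁻¹ ≠
4.15 g N per event); the per-event value 4.15 g is used and the
discrepancy logged. Deposition is spatially uniform over the grazed
field; patch-scale heterogeneity is out of scope. Volatilized N is
reported as a gaseous loss, never a soil input.

## Daily loop and budgets

Order per day: weather → management inputs (fertilizer, FYM, reseed) and
deposition → soil heat → plant development, assimilation,
respiration/partitioning, uptake/fixation, root growth, litterfall, cuts
→ PET, actual ET and the Richards step → solute transport → C/N
transformations → grazing intake and excreta → ledger bookkeeping. The
order is canonical: moving transport after transformations (or any other
reordering) changes outputs, and a golden-run test pins a one-year
summary at 10⁻⁶ relative tolerance. Each day the water ledger must close
within 10⁻³ mm and the soil/plant C and N ledgers within 10⁻⁶ kg ha⁻¹, or
the run aborts; annual budgets are calendar-year sums re-checked at
annual scale. Ammonium-nitrate applications volatilize 2 % of applied N
at spreading; FYM splits into available mineral N (default fraction 0.25)
and fresh-OM N. Reseeding incorporates the old sward into litter/fresh OM
(counted explicitly in the soil ledgers), starts the new species from
seedling mass after a 30-day fallow, and is the one day on which the
plant ledger is exempt from closure (seed mass appears from outside the
ledger). Runs start from field capacity with 60 t C ha⁻¹ of humus at C:N
10; no spin-up is applied by default — treatment comparisons share the
same initial state and forcing, so contrasts are interpretable even
though absolute pool trajectories still carry initialization transients.

## Synthetic data generator

Weather: sinusoidal seasonal tmax/tmin (site-like means 12.8/5.8 °C,
amplitude 5.5 °C) with Gaussian noise; precipitation occurrence is a
two-state Markov chain (p_wet|wet 0.65, p_wet|dry 0.35) with exponential
wet-day amounts scaled so the long-run annual total matches the 1029 mm
target within 10 %; radiation is seasonal, damped 30 % on wet days; wind
and humidity are noisy baselines. Ensembles differ only by sub-seed
(default 20 members at desk scale rather than 100). Observations are the
truth simulation plus multiplicative Gaussian noise: weekly soil
moisture, daily flume flux (runoff + drainage, with a 0.05 mm detection
floor) and per-cut biomass as 5 replicates with mean/SD/SE so the
95 %-confidence statistics are computable. What the generator does not
emulate: spatial heterogeneity, autocorrelated sensor drift, skewed
observation errors, sub-daily hydrograph shape, and real management noise
— so green tests demonstrate internal consistency and known-truth
recovery, not fidelity to any particular site.

Treatment fixtures share soil and weather and differ only in species and
management: fertilized permanent ryegrass (180 kg N ha⁻¹ yr⁻¹ in three
splits), grass/clover at half fertilizer with fixation enabled, and a
deep-rooting reseed in the first spring. Each also receives annual FYM
(10 t ha⁻¹, 60 kg N), two cuts and a summer beef-grazing window.

## Evaluation statistics

For observed O and simulated P: r is Pearson; RMSE = (100/Ō)√(Σ(Pᵢ−Oᵢ)²/n);
EF = 1 − Σ(Pᵢ−Oᵢ)²/Σ(Oᵢ−Ō)²; the reported "R²" is the scatter ratio
Σ(Oᵢ−Ō)²/Σ(Pᵢ−Ō)², which can exceed 1; RE = 100(Ō−P̄)/Ō and
MD = mean(O−P), both negative under over-estimation; ME is the maximum
absolute error (the absolute convention is used; tabulated MEs in this
field are positive). RMSE95 uses per-observation 95 % half-widths
t₀.₉₇₅,ν·SEᵢ: RMSE95 = (100/Ō)√(Σhᵢ²/n); RE95 is the mean half-width as a
percentage of Ō (the reference formulation does not print this formula;
this convention is the package's). EF is reported as undefined (NaN) for
zero observed variance, percentage statistics for Ō = 0. Correlation
significance is the two-tailed t-test with n−2 df; MD bias significance a
paired t-test at 5 %. One-way ANOVA uses the standard decomposition with
LSD_α = t_{α/2,df_w}√(2MS_w/n) (harmonic-mean n with a warning when
unbalanced). scipy supplies the t and F distributions only; the
statistics themselves are computed directly and cross-checked in tests
against independent direct-summation oracles and `scipy.stats.f_oneway` /
`pearsonr`.

## Problem sizes

The test suite runs one 30-year single-field simulation (the conservation
suite), three 3–4-year treatment runs, and sub-minute kernels elsewhere;
`scripts/acceptance.py` uses 5-year treatment runs and a 10-member
one-year ensemble. These sizes were chosen as the smallest that exercise
multi-decade accumulation, full seasonal cycles and ensemble averaging.

## Known limitations

No snow, no preferential flow, no 2-D/3-D routing; thermal properties
uncoupled from moisture; no microbial biomass state, CH₄, pH or P
dynamics; no animal live-weight gain or housed-period manure; mixtures
approximated by a single parameterized sward; fixed CO₂; management held
constant across climate scenarios by design. Scenario magnitudes from the
synthetic fixtures are internally consistent but not calibrated to any
real site; only structural contrasts between treatments should be
interpreted.
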