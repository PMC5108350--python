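"""Daily grass and legume sward growth.

Growth is driven by a development index (DI): thermal time accumulated
above a species base temperature since sowing or the last cut, normalized
by a thermal-time constant. The DI keys the partitioning of photosynthate
among leaf, stem and root through piecewise-linear interpolation between
breakpoint coefficient sets.

Carbon assimilation uses a radiation-use-efficiency (RUE) formulation:
GPP = RUE x intercepted radiation (Beer's law on LAI) x temperature
response x min(water stress, N stress) x CO2 response, with the CO2
response equal to 1 at the 695 mg m-3 reference concentration. Maintenance
respiration is proportional to organ C, growth respiration a fixed fraction
of the remaining assimilate. N uptake is distributed over soil layers in
proportion to root fraction and mineral N; legumes fix N to fill any
remaining deficit up to a maximum daily rate. Root depth extends with
thermal time to a species maximum, with an exponential-with-depth root
distribution truncated at the current depth.

Masses are kg ha-1 (C or N); dry matter converts at a C fraction of 0.45.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpeciesParams",
    "PlantState",
    "PlantDailyFluxes",
    "SPECIES_REGISTRY",
    "update_development",
    "assimilate",
    "respire_and_partition",
    "uptake_and_fix",
    "grow_roots",
    "litterfall",
    "cut",
    "new_sward",
]

C_FRACTION_DM = 0.45
CO2_REFERENCE_MG_M3 = 695.0


@dataclass(frozen=True)
class SpeciesParams:
    """Species parameterization; shipped sets are calibration fixtures."""

    name: str
    base_temperature_c: float = 4.0
    thermal_time_norm_cd: float = 1000.0       # degC d to advance DI by 1
    # (DI breakpoint, (leaf, stem, root) partition fractions)
    partition_breakpoints: tuple = (
        (0.0, (0.45, 0.15, 0.40)),
        (0.5, (0.55, 0.25, 0.20)),
        (1.0, (0.40, 0.45, 0.15)),
        (2.0, (0.30, 0.55, 0.15)),
    )
    rue_g_c_mj: float = 1.5
    maintenance_resp_per_day: float = 0.010    # fraction of organ C at 20 degC
    growth_resp_fraction: float = 0.25
    max_root_depth_m: float = 0.4
    root_extension_m_per_cd: float = 5e-4      # m per degC d
    root_shape_per_m: float = 3.0              # exponential decay of root density
    legume: bool = False
    max_fixation_kg_n_ha_d: float = 0.0
    leaf_n_conc: float = 0.030                 # g N per g DM targets
    stem_n_conc: float = 0.015
    root_n_conc: float = 0.012
    sla_ha_kg_dm: float = 0.02                 # LAI per kg leaf DM ha-1
    stubble_kg_dm_ha: float = 1000.0
    leaf_turnover_per_day: float = 0.003
    root_turnover_per_day: float = 0.002
    t_opt_low_c: float = 18.0
    t_opt_high_c: float = 25.0
    t_max_c: float = 40.0

    def __post_init__(self) -> None:
        for di, fr in self.partition_breakpoints:
            if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError("partition fractions must be >= 0 and sum to 1")
        if self.max_root_depth_m <= 0:
            raise ValueError("max rooting depth must be positive")

    def partition_at(self, di: float) -> np.ndarray:
        """Interpolate (leaf, stem, root) fractions at a development index."""
        bps = self.partition_breakpoints
        if di <= bps[0][0]:
            return np.array(bps[0][1])
        for (d0, f0), (d1, f1) in zip(bps, bps[1:]):
            if di <= d1:
                w = (di - d0) / (d1 - d0)
                return (1 - w) * np.array(f0) + w * np.array(f1)
        return np.array(bps[-1][1])

    def temperature_response(self, t_c: float) -> float:
        """0 below base, ramping to 1 over [t_opt_low, t_opt_high], 0 at t_max."""
        if t_c <= self.base_temperature_c or t_c >= self.t_max_c:
            return 0.0
        if t_c < self.t_opt_low_c:
            return (t_c - self.base_temperature_c) / (self.t_opt_low_c - self.base_temperature_c)
        if t_c <= self.t_opt_high_c:
            return 1.0
        return (self.t_max_c - t_c) / (self.t_max_c - self.t_opt_high_c)


SPECIES_REGISTRY: dict[str, SpeciesParams] = {
    "ryegrass": SpeciesParams(name="ryegrass"),
    "white_clover": SpeciesParams(
        name="white_clover", legume=True, max_fixation_kg_n_ha_d=2.0,
        rue_g_c_mj=1.3, leaf_n_conc=0.040, max_root_depth_m=0.3,
    ),
    "festulolium": SpeciesParams(
        name="festulolium", max_root_depth_m=1.0, root_extension_m_per_cd=8e-4,
        root_shape_per_m=2.0, rue_g_c_mj=1.6,
    ),
}


@dataclass
class PlantState:
    """Sward state: DI, organ C/N masses, LAI, rooting."""

    di: float = 0.0
    leaf_c: float = 0.0
    stem_c: float = 0.0
    root_c: float = 0.0
    leaf_n: float = 0.0
    stem_n: float = 0.0
    root_n: float = 0.0
    root_depth_m: float = 0.05
    root_fraction: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self) -> None:
        self.root_fraction = np.asarray(self.root_fraction, dtype=float)
        for name in ("leaf_c", "stem_c", "root_c", "leaf_n", "stem_n", "root_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def lai(self) -> float:
        # derived from leaf DM via specific leaf area at the registry default
        return self.leaf_c / C_FRACTION_DM * 0.02

    def lai_for(self, params: SpeciesParams) -> float:
        return self.leaf_c / C_FRACTION_DM * params.sla_ha_kg_dm

    @property
    def plant_c(self) -> float:
        return self.leaf_c + self.stem_c + self.root_c

    @property
    def plant_n(self) -> float:
        return self.leaf_n + self.stem_n + self.root_n

    @property
    def aboveground_dm(self) -> float:
        return (self.leaf_c + self.stem_c) / C_FRACTION_DM

    def copy(self) -> "PlantState":
        return PlantState(
            di=self.di, leaf_c=self.leaf_c, stem_c=self.stem_c, root_c=self.root_c,
            leaf_n=self.leaf_n, stem_n=self.stem_n, root_n=self.root_n,
            root_depth_m=self.root_depth_m, root_fraction=self.root_fraction.copy(),
        )


@dataclass
class PlantDailyFluxes:
    gpp: float = 0.0                   # kg C ha-1 d-1
    respiration: float = 0.0
    growth_leaf_c: float = 0.0
    growth_stem_c: float = 0.0
    growth_root_c: float = 0.0
    n_uptake_by_layer: np.ndarray = field(default_factory=lambda: np.zeros(1))
    n_fixation: float = 0.0
    litter_c: float = 0.0              # above-ground litterfall
    litter_n: float = 0.0
    root_litter_c: float = 0.0
    root_litter_n: float = 0.0

    @property
    def n_uptake(self) -> float:
        return float(np.sum(self.n_uptake_by_layer))


def new_sward(params: SpeciesParams, n_layers: int, seedling_dm: float = 50.0) -> PlantState:
    """A freshly sown sward with a small seedling mass."""
    c = seedling_dm * C_FRACTION_DM
    rf = np.zeros(n_layers)
    rf[0] = 1.0
    return PlantState(
        di=0.0,
        leaf_c=0.5 * c, stem_c=0.2 * c, root_c=0.3 * c,
        leaf_n=0.5 * seedling_dm * params.leaf_n_conc,
        stem_n=0.2 * seedling_dm * params.stem_n_conc,
        root_n=0.3 * seedling_dm * params.root_n_conc,
        root_depth_m=0.05, root_fraction=rf,
    )


def update_development(state: PlantState, day, params: SpeciesParams) -> PlantState:
    """Advance DI by the day's thermal time over the normalizer."""
    s = state.copy()
    tmean = 0.5 * (day.tmax_c + day.tmin_c)
    s.di += max(0.0, tmean - params.base_temperature_c) / params.thermal_time_norm_cd
    return s


def assimilate(
    state: PlantState,
    day,
    water_stress: float,
    n_stress: float,
    params: SpeciesParams,
    co2_mg_m3: float = CO2_REFERENCE_MG_M3,
) -> float:
    """Gross photosynthesis, kg C ha-1 d-1."""
    for name, v in (("water_stress", water_stress), ("n_stress", n_stress)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    lai = state.lai_for(params)
    intercepted = day.radiation_mj_m2 * (1.0 - math.exp(-0.5 * lai))
    tmean = 0.5 * (day.tmax_c + day.tmin_c)
    f_t = params.temperature_response(tmean)
    f_co2 = 1.0 + 0.4 * math.log(co2_mg_m3 / CO2_REFERENCE_MG_M3) if co2_mg_m3 > 0 else 0.0
    gpp_g_m2 = params.rue_g_c_mj * intercepted * f_t * min(water_stress, n_stress) * f_co2
    return max(0.0, gpp_g_m2 * 10.0)  # g C m-2 -> kg C ha-1


def respire_and_partition(
    state: PlantState, gpp: float, tmean_c: float, params: SpeciesParams
) -> tuple[PlantState, PlantDailyFluxes]:
    """Maintenance + growth respiration, then DI-keyed partitioning.

    Maintenance respiration is capped at GPP so the daily C flux ledger
    stays non-negative (no reserve remobilization is modelled).
    """
    if gpp < 0:
        raise ValueError("gpp must be non-negative")
    s = state.copy()
    fx = PlantDailyFluxes()
    fx.gpp = gpp
    f_t = 2.0 ** ((tmean_c - 20.0) / 10.0)
    maint = min(gpp, params.maintenance_resp_per_day * s.plant_c * f_t)
    after_maint = gpp - maint
    growth_resp = params.growth_resp_fraction * after_maint
    net = after_maint - growth_resp
    fx.respiration = maint + growth_resp

    frac = params.partition_at(s.di)
    fx.growth_leaf_c, fx.growth_stem_c, fx.growth_root_c = (net * frac).tolist()
    s.leaf_c += fx.growth_leaf_c
    s.stem_c += fx.growth_stem_c
    s.root_c += fx.growth_root_c
    return s, fx


def n_demand(state: PlantState, params: SpeciesParams) -> float:
    """N required to bring all organs to their target N concentration."""
    target = (
        state.leaf_c / C_FRACTION_DM * params.leaf_n_conc
        + state.stem_c / C_FRACTION_DM * params.stem_n_conc
        + state.root_c / C_FRACTION_DM * params.root_n_conc
    )
    return max(0.0, target - state.plant_n)


def n_stress(state: PlantState, params: SpeciesParams) -> float:
    """Plant N status in [0, 1]: actual over target whole-plant N."""
    target = (
        state.leaf_c / C_FRACTION_DM * params.leaf_n_conc
        + state.stem_c / C_FRACTION_DM * params.stem_n_conc
        + state.root_c / C_FRACTION_DM * params.root_n_conc
    )
    if target <= 0:
        return 1.0
    return float(min(1.0, state.plant_n / target))


def uptake_and_fix(
    state: PlantState,
    mineral_n_by_layer: np.ndarray | Sequence[float],
    demand: float,
    params: SpeciesParams,
    max_uptake_fraction: float = 0.5,
) -> tuple[PlantState, PlantDailyFluxes]:
    """Distribute N uptake over layers; legumes fix the remaining deficit.

    Per-layer uptake is proportional to root fraction x mineral N (capped at
    ``max_uptake_fraction`` of a layer's mineral N per day), scaled down if
    the total would exceed demand. Fixation covers what uptake cannot, up to
    the species maximum; non-legumes fix nothing. Acquired N is allocated to
    organs in proportion to their N deficits.
    """
    if demand < 0:
        raise ValueError("demand must be non-negative")
    s = state.copy()
    fx = PlantDailyFluxes()
    mineral = np.asarray(mineral_n_by_layer, dtype=float)
    rf = s.root_fraction
    if mineral.shape != rf.shape:
        raise ValueError("mineral N vector must match root fraction layers")
    potential = max_uptake_fraction * mineral * rf
    total_pot = potential.sum()
    if total_pot > demand > 0:
        potential = potential * (demand / total_pot)
    elif demand == 0:
        potential = np.zeros_like(potential)
    fx.n_uptake_by_layer = potential
    uptake = float(potential.sum())

    fix = 0.0
    if params.legume:
        fix = min(params.max_fixation_kg_n_ha_d, max(0.0, demand - uptake))
    fx.n_fixation = fix

    acquired = uptake + fix
    deficits = np.array([
        max(0.0, s.leaf_c / C_FRACTION_DM * params.leaf_n_conc - s.leaf_n),
        max(0.0, s.stem_c / C_FRACTION_DM * params.stem_n_conc - s.stem_n),
        max(0.0, s.root_c / C_FRACTION_DM * params.root_n_conc - s.root_n),
    ])
    if deficits.sum() > 0:
        share = deficits / deficits.sum()
    else:
        share = np.array([0.5, 0.25, 0.25])
    s.leaf_n += acquired * share[0]
    s.stem_n += acquired * share[1]
    s.root_n += acquired * share[2]
    return s, fx


def root_fractions(depth_m: float, layer_thickness_m: Sequence[float], shape_per_m: float) -> np.ndarray:
    """Discretize an exponential root-density profile truncated at depth."""
    dz = np.asarray(layer_thickness_m, dtype=float)
    tops = np.concatenate([[0.0], np.cumsum(dz)[:-1]])
    bots = np.cumsum(dz)
    b = shape_per_m
    # integral of exp(-b z) over the rooted part of each layer
    lo = np.minimum(tops, depth_m)
    hi = np.minimum(bots, depth_m)
    w = np.where(hi > lo, (np.exp(-b * lo) - np.exp(-b * hi)) / b, 0.0)
    if w.sum() <= 0:
        w = np.zeros_like(dz)
        w[0] = 1.0
        return w
    return w / w.sum()


def grow_roots(
    state: PlantState, day, params: SpeciesParams, layer_thickness_m: Sequence[float]
) -> PlantState:
    """Extend root depth with thermal time and refresh layer fractions."""
    s = state.copy()
    tmean = 0.5 * (day.tmax_c + day.tmin_c)
    dd = max(0.0, tmean - params.base_temperature_c)
    s.root_depth_m = min(
        params.max_root_depth_m, s.root_depth_m + params.root_extension_m_per_cd * dd
    )
    s.root_fraction = root_fractions(s.root_depth_m, layer_thickness_m, params.root_shape_per_m)
    return s


def litterfall(state: PlantState, params: SpeciesParams) -> tuple[PlantState, PlantDailyFluxes]:
    """First-order turnover of leaf (to litter) and root (to fresh OM)."""
    s = state.copy()
    fx = PlantDailyFluxes()
    kl, kr = params.leaf_turnover_per_day, params.root_turnover_per_day
    fx.litter_c = s.leaf_c * kl
    fx.litter_n = s.leaf_n * kl
    fx.root_litter_c = s.root_c * kr
    fx.root_litter_n = s.root_n * kr
    s.leaf_c -= fx.litter_c
    s.leaf_n -= fx.litter_n
    s.root_c -= fx.root_litter_c
    s.root_n -= fx.root_litter_n
    return s, fx


def cut(state: PlantState, params: SpeciesParams) -> tuple[PlantState, float]:
    """Remove above-ground biomass above stubble; reset DI.

    Returns (state, removed dry matter in kg DM ha-1). Roots are untouched;
    removed N leaves with the herbage at its current concentration.
    """
    s = state.copy()
    above_dm = s.aboveground_dm
    if above_dm <= params.stubble_kg_dm_ha:
        return s, 0.0
    removed_dm = above_dm - params.stubble_kg_dm_ha
    keep = params.stubble_kg_dm_ha / above_dm
    s.leaf_c *= keep
    s.stem_c *= keep
    s.leaf_n *= keep
    s.stem_n *= keep
    s.di = 0.0
    return s, removed_dm


def graze(state: PlantState, demand_kg_dm_ha: float, params: SpeciesParams) -> tuple[PlantState, float]:
    """Remove herbage for grazing intake, capped at the mass above stubble."""
    s = state.copy()
    available = max(0.0, s.aboveground_dm - params.stubble_kg_dm_ha)
    removed = min(demand_kg_dm_ha, available)
    if removed > 0 and s.aboveground_dm > 0:
        keep = 1.0 - removed / s.aboveground_dm
        s.leaf_c *= keep
        s.stem_c *= keep
        s.leaf_n *= keep
        s.stem_n *= keep
    return s, removed
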