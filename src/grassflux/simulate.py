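"""Management calendar, the coupled daily simulation loop, and budgets.

The daily loop couples the component models in a fixed, canonical order:

1. weather for the day
2. management inputs (fertilizer, FYM, reseeding) into the soil pools
3. soil heat conduction forced by air temperature
4. plant development, assimilation, respiration/partitioning, N uptake and
   fixation, root growth, litterfall, scheduled cuts
5. potential and actual evapotranspiration, then the Richards water step
6. solute transport with the day's water fluxes
7. soil C/N transformations (decomposition, nitrification, denitrification)
8. livestock intake and excreta during grazing periods
9. balance bookkeeping (daily closure of the water, C and N ledgers)

Reordering these stages changes results; the shipped order is part of the
model definition and is pinned by a golden-run test.

Outputs: a daily table (DataFrame / CSV), per-calendar-year AnnualBudget
ledgers (JSON-serializable) and run metadata including a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date as Date, timedelta
from pathlib import Path
import numpy as np
import pandas as pd

from . import plants, soil_cn, soil_water
from .livestock import (
    ExcretaReturn, LivestockSpec, StockingPeriod, daily_intake, excreta_returns,
    load_default_specs,
)
from .plants import SPECIES_REGISTRY
from .soil_cn import CNDailyFluxes, CNParams, LayerCNPools, EnvModifiers
from .soil_water import SoilColumnState, SoilLayerPhysical
from .weather import WeatherSeries

__all__ = [
    "ManagementEvent",
    "RunConfig",
    "AnnualBudget",
    "TreatmentScenario",
    "SimulationResult",
    "simulate",
    "annual_budget",
    "compare_treatments",
]

log = logging.getLogger(__name__)

WATER_CLOSURE_TOL_MM = 1e-3
MASS_CLOSURE_TOL = 1e-6       # kg ha-1 d-1 on the C and N ledgers

TREATMENT_NAMES = ("sustainable_intensification", "increased_legumes", "planned_reseeding")


@dataclass(frozen=True)
class ManagementEvent:
    date: Date
    kind: str                         # fertilizer | fym | cut | reseed
    amount_kg_n_ha: float = 0.0       # fertilizer N
    product: str = "ammonium_nitrate"
    fym_mass_kg_ha: float = 0.0
    fym_total_n_kg_ha: float = 0.0
    fym_available_n_fraction: float = 0.25
    species: str = ""                 # for reseed

    def __post_init__(self) -> None:
        if self.kind not in ("fertilizer", "fym", "cut", "reseed"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if min(self.amount_kg_n_ha, self.fym_mass_kg_ha, self.fym_total_n_kg_ha) < 0:
            raise ValueError("event amounts must be non-negative")
        if not 0.0 <= self.fym_available_n_fraction <= 1.0:
            raise ValueError("FYM available-N fraction outside [0, 1]")


@dataclass(frozen=True)
class TreatmentScenario:
    """Maps a named treatment to its species/management deltas."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in TREATMENT_NAMES:
            raise ValueError(f"unknown treatment {self.name!r}")


@dataclass
class RunConfig:
    field_label: str
    soil_layers: list[SoilLayerPhysical]
    species: str
    events: list[ManagementEvent]
    stocking: list[StockingPeriod]
    weather: WeatherSeries
    start: Date
    end: Date
    seed: int = 0
    cn_params: CNParams = field(default_factory=CNParams)
    initial_theta: np.ndarray | None = None
    initial_humus_c_kg_ha: float = 60_000.0
    initial_humus_cn: float = 10.0
    initial_mineral_n_kg_ha: float = 30.0
    spinup_years: int = 0
    livestock_specs: dict[str, LivestockSpec] = field(default_factory=load_default_specs)
    reseed_fallow_days: int = 30

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("simulation end precedes start")
        wdates = self.weather.dates
        if pd.Timestamp(self.start) < wdates.iloc[0] or pd.Timestamp(self.end) > wdates.iloc[-1]:
            raise ValueError("simulation span not covered by weather series")
        for ev in self.events:
            if not self.start <= ev.date <= self.end:
                raise ValueError(f"event on {ev.date} outside simulation span")
        if self.species not in SPECIES_REGISTRY:
            raise ValueError(f"unknown species {self.species!r}")

    def config_hash(self) -> str:
        payload = {
            "field": self.field_label,
            "species": self.species,
            "start": str(self.start),
            "end": str(self.end),
            "seed": self.seed,
            "layers": [asdict(l) for l in self.soil_layers],
            "events": [
                {**{k: str(v) if isinstance(v, Date) else v for k, v in asdict(e).items()}}
                for e in self.events
            ],
            "stocking": [
                {**{k: str(v) if isinstance(v, Date) else v for k, v in asdict(s).items()}}
                for s in self.stocking
            ],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class AnnualBudget:
    """Calendar-year flux ledger, Jan 1 - Dec 31 sums."""

    year: int
    # carbon, kg C ha-1
    gpp: float = 0.0
    plant_respiration: float = 0.0
    soil_respiration: float = 0.0
    c_leached: float = 0.0
    offtake_c: float = 0.0
    delta_soc: float = 0.0
    delta_plant_c: float = 0.0
    # nitrogen, kg N ha-1
    n_deposition: float = 0.0
    n_fertilizer: float = 0.0
    n_fym: float = 0.0
    n_fixation: float = 0.0
    n_excreta: float = 0.0
    n_offtake: float = 0.0
    n_leached: float = 0.0
    n_runoff: float = 0.0
    n_gaseous: float = 0.0            # N2O + N2 + volatilized NH3
    delta_soil_n: float = 0.0
    delta_plant_n: float = 0.0
    # water, mm
    precipitation: float = 0.0
    et: float = 0.0
    runoff: float = 0.0
    drainage: float = 0.0
    percolation: float = 0.0
    delta_storage: float = 0.0

    def water_residual(self) -> float:
        return self.precipitation - (
            self.et + self.runoff + self.drainage + self.percolation + self.delta_storage
        )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationResult:
    daily: pd.DataFrame
    budgets: list[AnnualBudget]
    meta: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.daily.to_csv(out / "daily.csv", index=False, float_format="%.6g")
        with open(out / "annual_budget.json", "w") as fh:
            json.dump([b.as_dict() for b in self.budgets], fh, indent=1)
        with open(out / "run_meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1)


class BalanceError(RuntimeError):
    """A daily mass-balance ledger failed to close."""


def _wfps(theta: float, layer: SoilLayerPhysical) -> float:
    return min(1.0, theta / layer.theta_s)


def _water_stress(theta, layers, root_fraction) -> float:
    wp = np.array([l.theta_wp for l in layers])
    fc = np.array([l.theta_fc for l in layers])
    avail = np.clip((theta - wp) / (fc - wp), 0.0, 1.0)
    return float(np.clip(np.sum(avail * root_fraction), 0.0, 1.0))


def simulate(config: RunConfig) -> SimulationResult:
    """Run the coupled daily simulation over the configured span.

    Deterministic for a fixed config and seed. Raises BalanceError if any
    daily water/C/N ledger fails to close within tolerance.
    """
    layers = config.soil_layers
    n_layers = len(layers)
    dz = np.array([l.thickness_m for l in layers])
    cnp = config.cn_params

    # --- initial state ---------------------------------------------------
    theta0 = (
        np.asarray(config.initial_theta, dtype=float)
        if config.initial_theta is not None
        else np.array([l.theta_fc for l in layers])
    )
    soil = SoilColumnState(theta0, np.full(n_layers, 9.0))
    # humus distributed with depth; mineral N in the top layers
    humus_w = dz / dz.sum()
    pools = []
    for i in range(n_layers):
        pools.append(
            LayerCNPools(
                humus_c=config.initial_humus_c_kg_ha * humus_w[i],
                humus_n=config.initial_humus_c_kg_ha * humus_w[i] / config.initial_humus_cn,
                litter_c=500.0 * humus_w[i], litter_n=25.0 * humus_w[i],
                nh4=config.initial_mineral_n_kg_ha / 2.0 * humus_w[i],
                no3=config.initial_mineral_n_kg_ha / 2.0 * humus_w[i],
            )
        )
    species = SPECIES_REGISTRY[config.species]
    plant = plants.new_sward(species, n_layers, seedling_dm=1500.0)
    plant = plant.copy()
    plant.root_depth_m = min(0.3, species.max_root_depth_m)
    plant.root_fraction = plants.root_fractions(plant.root_depth_m, dz, species.root_shape_per_m)

    events_by_date: dict[Date, list[ManagementEvent]] = {}
    for ev in config.events:
        events_by_date.setdefault(ev.date, []).append(ev)

    reseed_until: Date | None = None
    rows = []
    day_count = (config.end - config.start).days + 1
    wdf = config.weather.data
    mask = (wdf["date"] >= pd.Timestamp(config.start)) & (wdf["date"] <= pd.Timestamp(config.end))
    weather_rows = wdf.loc[mask].reset_index(drop=True)
    if len(weather_rows) != day_count:
        raise ValueError("weather does not cover the simulation span contiguously")

    for i in range(day_count):
        wrow = weather_rows.iloc[i]
        today = wrow.date.date()
        day = _Day(today, wrow)
        tmean = 0.5 * (day.tmax_c + day.tmin_c)

        # opening totals for closure bookkeeping
        soil_n0 = sum(p.total_n() for p in pools)
        soil_c0 = sum(p.total_c() for p in pools)
        plant_c0, plant_n0 = plant.plant_c, plant.plant_n

        fert_n = fym_n = 0.0
        volatilized = 0.0
        cut_dm = 0.0
        reseed_c = reseed_n = 0.0  # old-sward biomass incorporated at reseeding
        # --- management inputs -------------------------------------------
        for ev in events_by_date.get(today, []):
            if ev.kind == "fertilizer":
                pools[0], vol = soil_cn.apply_fertilizer(pools[0], ev.amount_kg_n_ha, ev.product)
                fert_n += ev.amount_kg_n_ha
                volatilized += vol
            elif ev.kind == "fym":
                pools[0] = soil_cn.apply_fym(
                    pools[0], ev.fym_mass_kg_ha, ev.fym_total_n_kg_ha,
                    ev.fym_available_n_fraction, cnp,
                )
                fym_n += ev.fym_total_n_kg_ha
            elif ev.kind == "reseed":
                # terminate the sward: all biomass to litter / fresh OM
                reseed_c += plant.plant_c
                reseed_n += plant.plant_n
                pools[0].litter_c += plant.leaf_c + plant.stem_c
                pools[0].litter_n += plant.leaf_n + plant.stem_n
                for j in range(n_layers):
                    pools[j].fom_c += plant.root_c * plant.root_fraction[j]
                    pools[j].fom_n += plant.root_n * plant.root_fraction[j]
                species = SPECIES_REGISTRY[ev.species or config.species]
                plant = plants.new_sward(species, n_layers)
                reseed_until = today + timedelta(days=config.reseed_fallow_days)
        deposition_n: float
        pools[0], deposition_n = soil_cn.apply_deposition(pools[0], 1.0, cnp)

        growing = reseed_until is None or today >= reseed_until

        # --- soil heat ----------------------------------------------------
        soil = soil_water.fourier_heat_step(soil, layers, tmean)

        # --- plant processes ---------------------------------------------
        pfx = plants.PlantDailyFluxes(n_uptake_by_layer=np.zeros(n_layers))
        if growing:
            plant = plants.update_development(plant, day, species)
            ws = _water_stress(soil.theta, layers, plant.root_fraction)
            ns = plants.n_stress(plant, species)
            gpp = plants.assimilate(plant, day, ws, ns, species)
            plant, fx_g = plants.respire_and_partition(plant, gpp, tmean, species)
            demand = plants.n_demand(plant, species)
            mineral = np.array([p.nh4 + p.no3 for p in pools])
            plant, fx_u = plants.uptake_and_fix(plant, mineral, demand, species)
            # draw uptake from soil pools, NH4 and NO3 proportionally
            for j in range(n_layers):
                u = fx_u.n_uptake_by_layer[j]
                tot = pools[j].nh4 + pools[j].no3
                if u > 0 and tot > 0:
                    pools[j].nh4 -= u * pools[j].nh4 / tot
                    pools[j].no3 -= u * pools[j].no3 / tot
            plant = plants.grow_roots(plant, day, species, dz)
            plant, fx_l = plants.litterfall(plant, species)
            pools[0].litter_c += fx_l.litter_c
            pools[0].litter_n += fx_l.litter_n
            for j in range(n_layers):
                pools[j].fom_c += fx_l.root_litter_c * plant.root_fraction[j]
                pools[j].fom_n += fx_l.root_litter_n * plant.root_fraction[j]
            pfx.gpp = fx_g.gpp
            pfx.respiration = fx_g.respiration
            pfx.n_uptake_by_layer = fx_u.n_uptake_by_layer
            pfx.n_fixation = fx_u.n_fixation
            pfx.litter_c, pfx.litter_n = fx_l.litter_c, fx_l.litter_n
            pfx.root_litter_c, pfx.root_litter_n = fx_l.root_litter_c, fx_l.root_litter_n

        # scheduled cuts
        cut_n = cut_c = 0.0
        for ev in events_by_date.get(today, []):
            if ev.kind == "cut":
                n_before = plant.leaf_n + plant.stem_n
                c_before = plant.leaf_c + plant.stem_c
                plant, removed = plants.cut(plant, species)
                cut_dm += removed
                cut_c += c_before - (plant.leaf_c + plant.stem_c)
                cut_n += n_before - (plant.leaf_n + plant.stem_n)

        # --- ET + water step ---------------------------------------------
        lai = plant.lai_for(species) if growing else 0.0
        pet = soil_water.potential_evapotranspiration(day, lai)
        et_by_layer = soil_water.actual_et(pet, soil, layers, plant.root_fraction)
        water_before = soil.theta * dz * 1000.0
        soil, wflux = soil_water.richards_step(
            soil, layers, day.precip_mm, et_by_layer, 1.0, drain_at_bottom=True
        )
        if abs(wflux.closure_residual_mm()) > WATER_CLOSURE_TOL_MM:
            raise BalanceError(
                f"{today}: water closure residual {wflux.closure_residual_mm():.3e} mm"
            )

        # --- solute transport --------------------------------------------
        # interlayer downward flows reconstructed from continuity
        inter = np.zeros(n_layers - 1)
        out_flow = wflux.drainage_mm + wflux.percolation_mm
        # back-calculate: flow below layer i = inflow - d(storage) - et, top down
        inflow = wflux.infiltration_mm
        water_after = soil.theta * dz * 1000.0
        for j in range(n_layers - 1):
            q = inflow - (water_after[j] - water_before[j]) - et_by_layer[j]
            inter[j] = max(0.0, q)
            inflow = inter[j]
        pools, tfx = soil_cn.transport_solutes(
            pools, water_before, inter, out_flow, wflux.runoff_mm, dz, cnp
        )

        # --- C/N transformations -----------------------------------------
        day_cn = CNDailyFluxes()
        day_cn.add(tfx)
        for j in range(n_layers):
            mods = EnvModifiers(
                f_t=soil_cn.temperature_response(soil.temperature_c[j], cnp.q10, cnp.t_ref),
                f_w=soil_cn.moisture_response(_wfps(soil.theta[j], layers[j]), cnp.nitrif_wfps_opt),
                wfps=_wfps(soil.theta[j], layers[j]),
            )
            pools[j], fx_d = soil_cn.decompose(pools[j], mods, 1.0, cnp)
            pools[j], fx_n = soil_cn.nitrify(pools[j], mods, 1.0, cnp)
            pools[j], fx_dn = soil_cn.denitrify(pools[j], mods, 1.0, cnp, fx_d.het_co2_c)
            for fx in (fx_d, fx_n, fx_dn):
                day_cn.add(fx)

        # --- livestock ----------------------------------------------------
        graze_dm = 0.0
        excreta = ExcretaReturn(0, 0, 0, 0, 0, 0, 0)
        for sp in config.stocking:
            if sp.covers(today) and sp.head_count > 0:
                spec = config.livestock_specs[sp.animal_type]
                demand_dm = daily_intake(spec, sp)
                n_before = plant.leaf_n + plant.stem_n
                c_before = plant.leaf_c + plant.stem_c
                plant, removed = plants.graze(plant, demand_dm, species)
                if removed < demand_dm - 1e-9:
                    log.debug("%s: grazing shortfall %.1f kg DM", today, demand_dm - removed)
                graze_dm += removed
                cut_c += c_before - (plant.leaf_c + plant.stem_c)
                cut_n += n_before - (plant.leaf_n + plant.stem_n)
                ret = excreta_returns(spec, sp)
                pools[0] = soil_cn.apply_excreta(pools[0], ret)
                excreta = ExcretaReturn(
                    *(getattr(excreta, f) + getattr(ret, f) for f in (
                        "urine_nh4_n", "urine_don", "faecal_organic_n",
                        "faecal_nh4_n", "faecal_don", "volatilized_n", "dung_c",
                    ))
                )

        # --- bookkeeping ---------------------------------------------------
        soil_n1 = sum(p.total_n() for p in pools)
        soil_c1 = sum(p.total_c() for p in pools)
        n_inputs = (
            fert_n - volatilized + fym_n + deposition_n + excreta.total_soil_n
            + pfx.litter_n + pfx.root_litter_n + reseed_n
        )
        n_outputs = (
            pfx.n_uptake + day_cn.n2o + day_cn.n2 + day_cn.n_leached + day_cn.n_runoff
        )
        n_resid = (soil_n1 - soil_n0) - (n_inputs - n_outputs)
        if abs(n_resid) > MASS_CLOSURE_TOL:
            raise BalanceError(f"{today}: soil N ledger residual {n_resid:.3e} kg ha-1")
        c_inputs = pfx.litter_c + pfx.root_litter_c + excreta.dung_c + reseed_c
        for ev in events_by_date.get(today, []):
            if ev.kind == "fym":
                c_inputs += ev.fym_mass_kg_ha * cnp.fym_c_fraction
        c_outputs = day_cn.het_co2_c + day_cn.doc_leached + day_cn.doc_runoff
        c_resid = (soil_c1 - soil_c0) - (c_inputs - c_outputs)
        if abs(c_resid) > MASS_CLOSURE_TOL:
            raise BalanceError(f"{today}: soil C ledger residual {c_resid:.3e} kg ha-1")
        # the plant ledger is re-seeded from seed mass at reseeding
        reseed_today = reseed_c > 0 or any(
            ev.kind == "reseed" for ev in events_by_date.get(today, [])
        )

        plant_c_resid = (plant.plant_c - plant_c0) - (
            pfx.gpp - pfx.respiration - pfx.litter_c - pfx.root_litter_c - cut_c
        )
        plant_n_resid = (plant.plant_n - plant_n0) - (
            pfx.n_uptake + pfx.n_fixation - pfx.litter_n - pfx.root_litter_n - cut_n
        )
        if not reseed_today and (
            abs(plant_c_resid) > MASS_CLOSURE_TOL or abs(plant_n_resid) > MASS_CLOSURE_TOL
        ):
            raise BalanceError(
                f"{today}: plant ledger residual C {plant_c_resid:.3e} / N {plant_n_resid:.3e}"
            )

        rows.append({
            "date": today,
            "tmean_c": tmean,
            "precip_mm": day.precip_mm,
            "aet_mm": wflux.aet_mm,
            "runoff_mm": wflux.runoff_mm,
            "drainage_mm": wflux.drainage_mm,
            "percolation_mm": wflux.percolation_mm,
            "delta_storage_mm": wflux.delta_storage_mm,
            "water_residual_mm": wflux.closure_residual_mm(),
            "theta_top": soil.theta[0],
            "theta_profile_mean": float(np.average(soil.theta, weights=dz)),
            "soil_temp_top_c": soil.temperature_c[0],
            "gpp_kg_c_ha": pfx.gpp,
            "plant_resp_kg_c_ha": pfx.respiration,
            "het_co2_kg_c_ha": day_cn.het_co2_c,
            "doc_leached_kg_c_ha": day_cn.doc_leached + day_cn.doc_runoff,
            "offtake_c_kg_c_ha": cut_c,
            "offtake_n_kg_n_ha": cut_n,
            "cut_dm_kg_ha": cut_dm,
            "graze_dm_kg_ha": graze_dm,
            "n_uptake_kg_n_ha": pfx.n_uptake,
            "n_fixation_kg_n_ha": pfx.n_fixation,
            "n_fertilizer_kg_n_ha": fert_n,
            "n_fym_kg_n_ha": fym_n,
            "n_deposition_kg_n_ha": deposition_n,
            "n_excreta_kg_n_ha": excreta.total_soil_n,
            "n_volatilized_kg_n_ha": volatilized + excreta.volatilized_n,
            "n2o_kg_n_ha": day_cn.n2o,
            "n2_kg_n_ha": day_cn.n2,
            "n_leached_kg_n_ha": day_cn.n_leached,
            "n_runoff_kg_n_ha": day_cn.n_runoff,
            "nitrification_kg_n_ha": day_cn.nitrification,
            "denitrification_kg_n_ha": day_cn.denitrification,
            "soil_n_resid": n_resid,
            "soil_c_resid": c_resid,
            "plant_c_kg_ha": plant.plant_c,
            "plant_n_kg_ha": plant.plant_n,
            "lai": plant.lai_for(species) if growing else 0.0,
            "root_depth_m": plant.root_depth_m,
            "soil_c_kg_ha": soil_c1,
            "soil_n_kg_ha": soil_n1,
            "aboveground_dm_kg_ha": plant.aboveground_dm,
        })

    daily = pd.DataFrame(rows)
    daily["date"] = pd.to_datetime(daily["date"])
    budgets = [
        annual_budget(daily, int(y))
        for y in sorted(daily["date"].dt.year.unique())
        if _year_complete(daily, int(y))
    ]
    meta = {
        "field": config.field_label,
        "species": config.species,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": "0.1.0",
        "start": str(config.start),
        "end": str(config.end),
    }
    return SimulationResult(daily=daily, budgets=budgets, meta=meta)


def _year_complete(daily: pd.DataFrame, year: int) -> bool:
    sub = daily[daily["date"].dt.year == year]
    ndays = 366 if (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)) else 365
    return len(sub) == ndays


class _Day:
    """Weather-day view over a DataFrame row (duck-typed WeatherDay)."""

    __slots__ = ("date", "tmax_c", "tmin_c", "precip_mm", "radiation_mj_m2", "wind_m_s", "rh_pct")

    def __init__(self, date: Date, row) -> None:
        self.date = date
        self.tmax_c = float(row.tmax_c)
        self.tmin_c = float(row.tmin_c)
        self.precip_mm = float(row.precip_mm)
        self.radiation_mj_m2 = float(row.radiation_mj_m2)
        self.wind_m_s = float(row.wind_m_s)
        self.rh_pct = float(row.rh_pct)


def annual_budget(daily: pd.DataFrame, year: int) -> AnnualBudget:
    """Sum the daily table into a calendar-year ledger."""
    sub = daily[daily["date"].dt.year == year]
    if sub.empty:
        raise ValueError(f"no rows for year {year}")
    s = sub.sum(numeric_only=True)
    b = AnnualBudget(
        year=year,
        gpp=s["gpp_kg_c_ha"],
        plant_respiration=s["plant_resp_kg_c_ha"],
        soil_respiration=s["het_co2_kg_c_ha"],
        c_leached=s["doc_leached_kg_c_ha"],
        offtake_c=s["offtake_c_kg_c_ha"],
        delta_soc=float(sub["soil_c_kg_ha"].iloc[-1] - sub["soil_c_kg_ha"].iloc[0]),
        delta_plant_c=float(sub["plant_c_kg_ha"].iloc[-1] - sub["plant_c_kg_ha"].iloc[0]),
        n_deposition=s["n_deposition_kg_n_ha"],
        n_fertilizer=s["n_fertilizer_kg_n_ha"],
        n_fym=s["n_fym_kg_n_ha"],
        n_fixation=s["n_fixation_kg_n_ha"],
        n_excreta=s["n_excreta_kg_n_ha"],
        n_offtake=s["offtake_n_kg_n_ha"],
        n_leached=s["n_leached_kg_n_ha"],
        n_runoff=s["n_runoff_kg_n_ha"],
        n_gaseous=s["n2o_kg_n_ha"] + s["n2_kg_n_ha"] + s["n_volatilized_kg_n_ha"],
        delta_soil_n=float(sub["soil_n_kg_ha"].iloc[-1] - sub["soil_n_kg_ha"].iloc[0]),
        delta_plant_n=float(sub["plant_n_kg_ha"].iloc[-1] - sub["plant_n_kg_ha"].iloc[0]),
        precipitation=s["precip_mm"],
        et=s["aet_mm"],
        runoff=s["runoff_mm"],
        drainage=s["drainage_mm"],
        percolation=s["percolation_mm"],
        delta_storage=s["delta_storage_mm"],
    )
    return b


def compare_treatments(results: dict[str, SimulationResult]) -> pd.DataFrame:
    """Tabulate mean annual budgets per treatment, plus pairwise differences
    against the first treatment."""
    rows = {}
    for name, res in results.items():
        if not res.budgets:
            raise ValueError(f"{name}: no complete calendar years")
        df = pd.DataFrame([b.as_dict() for b in res.budgets]).drop(columns="year")
        rows[name] = df.mean()
    table = pd.DataFrame(rows).T
    base = table.iloc[0]
    for name in table.index[1:]:
        table.loc[f"{name} - {table.index[0]}"] = table.loc[name] - base
    return table
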