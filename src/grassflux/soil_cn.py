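"""Coupled soil carbon and nitrogen pool dynamics per layer.

Organic matter is tracked in four pools — fresh organic matter (recent
residues, dung, FYM), litter, humus and dissolved organic matter — each with
C and N; inorganic N sits in ammonium and nitrate pools. Transformations:

* first-order decomposition of each organic pool, scaled by a Q10
  temperature response and a piecewise-linear moisture response on
  water-filled pore space (WFPS); decomposed C is partly retained (microbial
  efficiency) in a receiving pool and partly respired; N follows C, with the
  C:N balance deciding between net mineralization and immobilization;
* Michaelis-Menten nitrification of ammonium with an aeration factor
  declining above the optimal WFPS, emitting a fixed N2O fraction;
* denitrification of nitrate above a WFPS threshold, Michaelis-Menten in
  nitrate and limited by carbon availability (heterotrophic CO2 as proxy),
  with the N2O:N2 product split shifting to N2 as WFPS approaches 1;
* advective solute transport (nitrate, DOC, DON and an adsorption-limited
  fraction of ammonium) with the water fluxes, plus runoff losses from a
  shallow surface mixing depth.

All pools are kg ha-1 per layer; fluxes kg ha-1 d-1. Every operation
conserves mass exactly (to float round-off) and keeps pools non-negative.
Rate constants are calibration parameters, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np

__all__ = [
    "LayerCNPools",
    "CNDailyFluxes",
    "EnvModifiers",
    "CNParams",
    "FertilizerProduct",
    "FERTILIZER_PRODUCTS",
    "decompose",
    "nitrify",
    "denitrify",
    "transport_solutes",
    "apply_fertilizer",
    "apply_fym",
    "apply_excreta",
    "apply_deposition",
    "temperature_response",
    "moisture_response",
]


@dataclass
class LayerCNPools:
    """C and N pools of one soil layer, kg ha-1."""

    fom_c: float = 0.0
    fom_n: float = 0.0
    litter_c: float = 0.0
    litter_n: float = 0.0
    humus_c: float = 0.0
    humus_n: float = 0.0
    doc: float = 0.0
    don: float = 0.0
    nh4: float = 0.0
    no3: float = 0.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"pool {f.name} must be non-negative")

    def total_n(self) -> float:
        return self.fom_n + self.litter_n + self.humus_n + self.don + self.nh4 + self.no3

    def total_c(self) -> float:
        return self.fom_c + self.litter_c + self.humus_c + self.doc

    def copy(self) -> "LayerCNPools":
        return LayerCNPools(**{f.name: getattr(self, f.name) for f in dc_fields(self)})


@dataclass
class CNDailyFluxes:
    """One day of layer (or profile) C/N transformation fluxes, kg ha-1 d-1."""

    gross_mineralization: float = 0.0
    immobilization: float = 0.0
    nitrification: float = 0.0
    denitrification: float = 0.0
    n2o: float = 0.0
    n2: float = 0.0
    het_co2_c: float = 0.0
    no3_leached: float = 0.0
    nh4_leached: float = 0.0
    doc_leached: float = 0.0
    don_leached: float = 0.0
    no3_runoff: float = 0.0
    nh4_runoff: float = 0.0
    doc_runoff: float = 0.0
    don_runoff: float = 0.0

    def add(self, other: "CNDailyFluxes") -> None:
        for f in dc_fields(self):
            setattr(self, f.name, getattr(self, f.name) + getattr(other, f.name))

    @property
    def n_leached(self) -> float:
        return self.no3_leached + self.nh4_leached + self.don_leached

    @property
    def n_runoff(self) -> float:
        return self.no3_runoff + self.nh4_runoff + self.don_runoff


@dataclass(frozen=True)
class EnvModifiers:
    """Environmental rate modifiers for one layer."""

    f_t: float
    f_w: float
    wfps: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_t <= 3.0:
            raise ValueError("f_t outside (0, 3]")
        if not 0.0 <= self.f_w <= 1.0:
            raise ValueError("f_w outside [0, 1]")
        if not 0.0 <= self.wfps <= 1.0:
            raise ValueError("WFPS outside [0, 1]")


def temperature_response(t_c: float, q10: float = 2.0, t_ref: float = 20.0) -> float:
    """Q10 temperature response, clamped to the (0, 3] modifier range."""
    return float(min(3.0, q10 ** ((t_c - t_ref) / 10.0)))


def moisture_response(wfps: float, optimum: float = 0.6) -> float:
    """Piecewise-linear moisture response on WFPS: 0 at dryness, 1 at the
    optimum, declining to 0.2 at saturation (anaerobic limitation)."""
    wfps = min(1.0, max(0.0, wfps))
    if wfps <= optimum:
        return wfps / optimum
    return 1.0 - 0.8 * (wfps - optimum) / (1.0 - optimum)


@dataclass(frozen=True)
class CNParams:
    """Rate constants and routing parameters (calibration targets)."""

    k_humus: float = 8e-5          # d-1
    k_litter: float = 0.01
    k_fom: float = 0.05
    k_dom: float = 0.1
    microbial_efficiency: float = 0.45
    humus_cn: float = 10.0
    nitrif_vmax: float = 20.0      # kg N ha-1 d-1 per layer
    nitrif_km: float = 5.0         # kg N ha-1
    nitrif_n2o_fraction: float = 0.02
    nitrif_wfps_opt: float = 0.6
    denit_vmax: float = 10.0       # kg N ha-1 d-1 per layer
    denit_km: float = 10.0         # kg N ha-1
    denit_wfps_threshold: float = 0.62
    denit_c_half: float = 5.0      # kg CO2-C ha-1 d-1 half-saturation
    nh4_mobile_fraction: float = 0.10
    runoff_mixing_depth_m: float = 0.05
    deposition_kg_n_ha_yr: float = 15.0
    q10: float = 2.0
    t_ref: float = 20.0
    fym_c_fraction: float = 0.40   # C per unit FYM dry matter


# ---------------------------------------------------------------------------
# Decomposition

def decompose(
    pools: LayerCNPools, mods: EnvModifiers, dt: float = 1.0, params: CNParams = CNParams()
) -> tuple[LayerCNPools, CNDailyFluxes]:
    """First-order decay of the organic pools with C:N-balanced N routing.

    Decomposed C from fresh OM, litter and DOM is retained in humus at the
    microbial efficiency; decomposed humus C routes its retained share to
    DOM. Source-pool N is released as gross mineralization to NH4; the
    retained C demands N at the receiving pool's C:N ratio (immobilization,
    drawn from NH4 then NO3). If mineral N cannot meet the demand, the
    limiting pools' decomposition is scaled back proportionally.
    """
    p = pools.copy()
    fx = CNDailyFluxes()
    f = mods.f_t * mods.f_w

    # (source C, source N, rate, receiver): receiver "humus" or "dom"
    routes = [
        ("fom_c", "fom_n", params.k_fom, "humus"),
        ("litter_c", "litter_n", params.k_litter, "humus"),
        ("doc", "don", params.k_dom, "humus"),
        ("humus_c", "humus_n", params.k_humus, "dom"),
    ]
    e = params.microbial_efficiency
    decay = {}
    demand_total = 0.0
    release_total = 0.0
    for c_name, n_name, k, recv in routes:
        c0 = getattr(p, c_name)
        n0 = getattr(p, n_name)
        frac = 1.0 - np.exp(-k * f * dt)
        dc = c0 * frac
        dn = n0 * frac
        retained = e * dc
        demand = retained / params.humus_cn  # both receivers held near humus C:N
        decay[c_name] = (dc, dn, retained, demand, recv, n_name)
        demand_total += demand
        release_total += dn

    mineral_n = p.nh4 + p.no3
    net_demand = demand_total - release_total
    scale = 1.0
    if net_demand > mineral_n and net_demand > 0:
        scale = max(0.0, mineral_n / net_demand)

    for c_name, (dc, dn, retained, demand, recv, n_name) in decay.items():
        dc *= scale
        dn *= scale
        retained *= scale
        demand *= scale
        setattr(p, c_name, getattr(p, c_name) - dc)
        setattr(p, n_name, getattr(p, n_name) - dn)
        if recv == "humus":
            p.humus_c += retained
            p.humus_n += demand
        else:
            p.doc += retained
            p.don += demand
        fx.het_co2_c += dc - retained
        fx.gross_mineralization += dn
        fx.immobilization += demand

    # net mineral N change: released N in, immobilized N out (NH4 first)
    p.nh4 += fx.gross_mineralization
    need = fx.immobilization
    take_nh4 = min(need, p.nh4)
    p.nh4 -= take_nh4
    need -= take_nh4
    take_no3 = min(need, p.no3)
    p.no3 -= take_no3
    need -= take_no3
    if need > 1e-9:
        raise AssertionError("immobilization overdraw despite scaling")
    p.nh4 = max(0.0, p.nh4)
    p.no3 = max(0.0, p.no3)
    return p, fx


# ---------------------------------------------------------------------------
# Nitrification / denitrification

def nitrify(
    pools: LayerCNPools, mods: EnvModifiers, dt: float = 1.0, params: CNParams = CNParams()
) -> tuple[LayerCNPools, CNDailyFluxes]:
    """Michaelis-Menten NH4 -> NO3 with a fixed N2O emission fraction.

    The aeration factor is 1 up to the optimal WFPS and declines linearly to
    0 at saturation.
    """
    p = pools.copy()
    fx = CNDailyFluxes()
    if p.nh4 <= 0:
        return p, fx
    wfps = mods.wfps
    opt = params.nitrif_wfps_opt
    f_aer = 1.0 if wfps <= opt else max(0.0, (1.0 - wfps) / (1.0 - opt))
    rate = params.nitrif_vmax * p.nh4 / (params.nitrif_km + p.nh4) * mods.f_t * f_aer * dt
    rate = min(rate, p.nh4)
    n2o = params.nitrif_n2o_fraction * rate
    p.nh4 -= rate
    p.no3 += rate - n2o
    fx.nitrification = rate
    fx.n2o = n2o
    return p, fx


def denitrify(
    pools: LayerCNPools,
    mods: EnvModifiers,
    dt: float = 1.0,
    params: CNParams = CNParams(),
    het_co2_c: float = 0.0,
) -> tuple[LayerCNPools, CNDailyFluxes]:
    """NO3 -> N2O + N2 above the WFPS threshold.

    Rate is Michaelis-Menten in NO3, scaled by temperature, the excess WFPS
    above the threshold, and C availability (heterotrophic CO2 of the same
    step as a proxy). The N2O share of the products falls linearly to zero
    at full saturation; products always sum to the NO3 consumed.
    """
    p = pools.copy()
    fx = CNDailyFluxes()
    thr = params.denit_wfps_threshold
    if p.no3 <= 0 or mods.wfps < thr:
        return p, fx
    f_wfps = (mods.wfps - thr) / (1.0 - thr)
    f_c = het_co2_c / (het_co2_c + params.denit_c_half) if het_co2_c > 0 else 0.0
    rate = (
        params.denit_vmax * p.no3 / (params.denit_km + p.no3)
        * mods.f_t * f_wfps * f_c * dt
    )
    rate = min(rate, p.no3)
    n2o_share = min(1.0, max(0.0, (1.0 - mods.wfps) / (1.0 - thr)))
    p.no3 -= rate
    fx.denitrification = rate
    fx.n2o = rate * n2o_share
    fx.n2 = rate * (1.0 - n2o_share)
    return p, fx


# ---------------------------------------------------------------------------
# Solute transport

def transport_solutes(
    pools: Sequence[LayerCNPools],
    layer_water_mm: np.ndarray | Sequence[float],
    interlayer_flow_mm: np.ndarray | Sequence[float],
    bottom_out_mm: float,
    runoff_mm: float,
    layer_thickness_m: Sequence[float],
    params: CNParams = CNParams(),
) -> tuple[list[LayerCNPools], CNDailyFluxes]:
    """Advect mobile solutes with water (mixing-cell scheme).

    ``layer_water_mm`` is the water stored per layer before transport,
    ``interlayer_flow_mm[i]`` the downward flow across the interface below
    layer i (n-1 values), ``bottom_out_mm`` the flow leaving the profile
    (drainage or percolation). Outflow concentration is the layer's fully
    mixed concentration; the mobile fractions are 1 for NO3, DOC and DON and
    ``nh4_mobile_fraction`` for adsorbed NH4. Runoff carries solutes from a
    shallow surface mixing depth of the top layer. Mass is conserved.
    """
    n = len(pools)
    water = np.asarray(layer_water_mm, dtype=float)
    flow = np.asarray(interlayer_flow_mm, dtype=float)
    if water.shape != (n,) or flow.shape != (n - 1,):
        raise ValueError("water/flow arrays inconsistent with number of layers")
    out = [p.copy() for p in pools]
    fx = CNDailyFluxes()
    mobile = {
        "no3": 1.0, "nh4": params.nh4_mobile_fraction, "doc": 1.0, "don": 1.0,
    }

    # runoff losses from the surface mixing zone of the top layer
    if runoff_mm > 0 and water[0] > 0:
        mix_frac = min(1.0, params.runoff_mixing_depth_m / layer_thickness_m[0])
        for sol, mob in mobile.items():
            mass = getattr(out[0], sol) * mix_frac * mob
            conc = mass / water[0]
            loss = min(mass, conc * runoff_mm)
            setattr(out[0], sol, getattr(out[0], sol) - loss)
            setattr(fx, f"{sol}_runoff", getattr(fx, f"{sol}_runoff") + loss)

    # downward advection, top to bottom
    flows_out = np.append(flow, bottom_out_mm)
    for i in range(n):
        q = max(0.0, flows_out[i])
        if q <= 0 or water[i] <= 0:
            continue
        frac = min(1.0, q / water[i])
        for sol, mob in mobile.items():
            mass_mobile = getattr(out[i], sol) * mob
            moved = mass_mobile * frac
            setattr(out[i], sol, getattr(out[i], sol) - moved)
            if i < n - 1:
                setattr(out[i + 1], sol, getattr(out[i + 1], sol) + moved)
            else:
                setattr(fx, f"{sol}_leached", getattr(fx, f"{sol}_leached") + moved)
    return out, fx


# ---------------------------------------------------------------------------
# Inputs

@dataclass(frozen=True)
class FertilizerProduct:
    name: str
    nh4_fraction: float
    no3_fraction: float
    volatilization_fraction: float = 0.0  # NH3-N lost at application

    def __post_init__(self) -> None:
        if abs(self.nh4_fraction + self.no3_fraction - 1.0) > 1e-9:
            raise ValueError("NH4 + NO3 fractions must sum to 1")


# ammonium nitrate loses about 2% of applied N as NH3 at spreading
FERTILIZER_PRODUCTS: dict[str, FertilizerProduct] = {
    "ammonium_nitrate": FertilizerProduct("ammonium_nitrate", 0.5, 0.5, 0.02),
    "urea": FertilizerProduct("urea", 1.0, 0.0, 0.15),
    "nitrate": FertilizerProduct("nitrate", 0.0, 1.0, 0.0),
}


def apply_fertilizer(
    pools: LayerCNPools, amount_kg_n_ha: float, product: str = "ammonium_nitrate"
) -> tuple[LayerCNPools, float]:
    """Add fertilizer N to the (top-layer) mineral pools.

    Returns the updated pools and the N volatilized at application.
    """
    if amount_kg_n_ha < 0:
        raise ValueError("fertilizer amount must be non-negative")
    if product not in FERTILIZER_PRODUCTS:
        raise KeyError(f"unknown fertilizer product {product!r}")
    prod = FERTILIZER_PRODUCTS[product]
    p = pools.copy()
    vol = amount_kg_n_ha * prod.volatilization_fraction
    reaching = amount_kg_n_ha - vol
    p.nh4 += reaching * prod.nh4_fraction
    p.no3 += reaching * prod.no3_fraction
    return p, vol


def apply_fym(
    pools: LayerCNPools,
    mass_kg_ha: float,
    total_n_kg_ha: float,
    available_n_fraction: float = 0.25,
    params: CNParams = CNParams(),
) -> LayerCNPools:
    """Incorporate farmyard manure: the available-N fraction of total N goes
    to ammonium, the remainder to fresh-OM N; FYM C joins fresh-OM C."""
    if min(mass_kg_ha, total_n_kg_ha) < 0 or not 0 <= available_n_fraction <= 1:
        raise ValueError("invalid FYM event")
    p = pools.copy()
    p.nh4 += total_n_kg_ha * available_n_fraction
    p.fom_n += total_n_kg_ha * (1.0 - available_n_fraction)
    p.fom_c += mass_kg_ha * params.fym_c_fraction
    return p


def apply_excreta(pools: LayerCNPools, ret) -> LayerCNPools:
    """Deposit grazing excreta (an ``ExcretaReturn``) into the top layer:
    urine NH4/DON to the mineral and dissolved pools, faecal organic N and
    dung C to fresh OM."""
    p = pools.copy()
    p.nh4 += ret.urine_nh4_n + ret.faecal_nh4_n
    p.don += ret.urine_don + ret.faecal_don
    p.fom_n += ret.faecal_organic_n
    p.fom_c += ret.dung_c
    return p


def apply_deposition(
    pools: LayerCNPools, dt: float = 1.0, params: CNParams = CNParams()
) -> tuple[LayerCNPools, float]:
    """Constant atmospheric N deposition, split evenly NH4/NO3."""
    p = pools.copy()
    daily = params.deposition_kg_n_ha_yr / 365.0 * dt
    p.nh4 += daily / 2.0
    p.no3 += daily / 2.0
    return p, daily
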