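"""Layered soil water and heat transport.

Vertical water movement follows the Richards equation on a one-dimensional
column of soil layers, closed with van Genuchten-Mualem retention and
conductivity functions. The discretization is the mass-conservative mixed
(theta-h) form with backward-Euler time stepping, solved by Newton
iteration on matric potential with a backtracking line search; steps that
fail to converge are halved adaptively. Mualem conductivity is continued
linearly to Ks above effective saturation 0.99, where the closed form's
vertical tangent would otherwise defeat the implicit solve on wet clay.
The residual water content is set to half the wilting point, which doubles
as the solver's lower bound on theta.

Surface input infiltrates up to a ponded-Darcy capacity; the excess is
surface runoff. The lower boundary is free drainage (unit gradient). When a
field drain is configured at the bottom interface, the water crossing it is
reported as drainage (lateral loss to the drain network) rather than deep
percolation — the field-scale abstraction of a drained clay grassland where
a flume captures surface runoff plus drain flow.

Soil temperature follows Fourier heat conduction, backward Euler in time,
with the daily mean air temperature as the surface boundary and an
insulated lower boundary.

Internal units are metres and days; the public API speaks mm of water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import root as sp_root

__all__ = [
    "SoilLayerPhysical",
    "SoilColumnState",
    "DailyWaterFluxes",
    "PotentialET",
    "SolverError",
    "richards_step",
    "potential_evapotranspiration",
    "actual_et",
    "fourier_heat_step",
    "theta_from_potential",
    "potential_from_theta",
    "hydraulic_conductivity",
    "default_clay_layers",
]

SECONDS_PER_DAY = 86_400.0
STEFAN_BOLTZMANN_MJ = 4.903e-9  # MJ K-4 m-2 d-1
CANOPY_EXTINCTION = 0.5


class SolverError(RuntimeError):
    """Raised when the implicit water step cannot be converged."""


@dataclass(frozen=True)
class SoilLayerPhysical:
    """Physical and hydraulic description of one soil layer."""

    thickness_m: float
    theta_s: float
    theta_fc: float
    theta_wp: float
    k_sat_m_d: float
    vg_alpha_per_m: float = 3.6
    vg_n: float = 1.35
    bulk_density_kg_m3: float = 1100.0
    thermal_conductivity_w_mk: float = 1.2
    heat_capacity_j_m3k: float = 2.5e6

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_wp < self.theta_fc < self.theta_s < 1.0:
            raise ValueError("require 0 < theta_wp < theta_fc < theta_s < 1")
        if self.k_sat_m_d <= 0 or self.thickness_m <= 0:
            raise ValueError("k_sat and thickness must be positive")
        if self.vg_n <= 1.0 or self.vg_alpha_per_m <= 0:
            raise ValueError("van Genuchten parameters require alpha > 0, n > 1")

    @property
    def theta_r(self) -> float:
        """Residual water content; also the numerical floor on theta."""
        return self.theta_wp / 2.0

    @property
    def vg_m(self) -> float:
        return 1.0 - 1.0 / self.vg_n


def default_clay_layers() -> list[SoilLayerPhysical]:
    """A clayey drained-grassland profile used throughout the test fixtures."""
    mk = lambda dz, ks: SoilLayerPhysical(
        thickness_m=dz, theta_s=0.48, theta_fc=0.38, theta_wp=0.20,
        k_sat_m_d=ks, vg_alpha_per_m=3.6, vg_n=1.25,
    )
    return [mk(0.10, 0.30), mk(0.20, 0.15), mk(0.25, 0.08), mk(0.30, 0.05)]


# ---------------------------------------------------------------------------
# van Genuchten-Mualem constitutive relations (vectorized over layers)

def _vg_arrays(layers: Sequence[SoilLayerPhysical]):
    a = np.array([l.vg_alpha_per_m for l in layers])
    n = np.array([l.vg_n for l in layers])
    m = np.array([l.vg_m for l in layers])
    tr = np.array([l.theta_r for l in layers])
    ts = np.array([l.theta_s for l in layers])
    ks = np.array([l.k_sat_m_d for l in layers])
    return a, n, m, tr, ts, ks


def theta_from_potential(h: np.ndarray, layers: Sequence[SoilLayerPhysical]) -> np.ndarray:
    a, n, m, tr, ts, _ = _vg_arrays(layers)
    h = np.asarray(h, dtype=float)
    se = np.where(h < 0, (1.0 + (a * np.abs(h)) ** n) ** (-m), 1.0)
    return tr + (ts - tr) * se


def potential_from_theta(theta: np.ndarray, layers: Sequence[SoilLayerPhysical]) -> np.ndarray:
    a, n, m, tr, ts, _ = _vg_arrays(layers)
    se = np.clip((np.asarray(theta, dtype=float) - tr) / (ts - tr), 1e-9, 1.0)
    h = np.where(se < 1.0, -(1.0 / a) * (se ** (-1.0 / m) - 1.0) ** (1.0 / n), 0.0)
    return h


def _moisture_capacity(h: np.ndarray, layers: Sequence[SoilLayerPhysical]) -> np.ndarray:
    """dtheta/dh, the specific moisture capacity."""
    a, n, m, tr, ts, _ = _vg_arrays(layers)
    ah = a * np.abs(h)
    c = np.where(
        h < 0,
        (ts - tr) * a * n * m * ah ** (n - 1.0) * (1.0 + ah ** n) ** (-m - 1.0),
        0.0,
    )
    return np.maximum(c, 1e-9)


_SE_REG = 0.99  # Mualem K has a vertical tangent at saturation; ramp above this


def _mualem_k(se: np.ndarray, m: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Mualem conductivity with a linear ramp near saturation.

    For n < 2 the closed form has an infinite slope at Se = 1, which makes
    the implicit solve intractable on wet clay; above ``_SE_REG`` the curve
    is continued linearly to Ks (a standard regularization).
    """
    se = np.clip(se, 1e-9, 1.0)
    se_c = np.minimum(se, _SE_REG)
    k_unsat = ks * np.sqrt(se_c) * (1.0 - (1.0 - se_c ** (1.0 / m)) ** m) ** 2
    k_star = ks * np.sqrt(_SE_REG) * (1.0 - (1.0 - _SE_REG ** (1.0 / m)) ** m) ** 2
    ramp = k_star + (ks - k_star) * (se - _SE_REG) / (1.0 - _SE_REG)
    return np.where(se > _SE_REG, ramp, k_unsat)


def hydraulic_conductivity(theta: np.ndarray, layers: Sequence[SoilLayerPhysical]) -> np.ndarray:
    a, n, m, tr, ts, ks = _vg_arrays(layers)
    se = (np.asarray(theta, dtype=float) - tr) / (ts - tr)
    return _mualem_k(se, m, ks)




# ---------------------------------------------------------------------------
# State and flux containers

@dataclass
class SoilColumnState:
    """Per-layer water content (m3 m-3) and temperature (degC)."""

    theta: np.ndarray
    temperature_c: np.ndarray
    drain_depth_m: float | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).copy()
        self.temperature_c = np.asarray(self.temperature_c, dtype=float).copy()
        if self.theta.shape != self.temperature_c.shape:
            raise ValueError("theta and temperature must have one value per layer")
        if not np.all(np.isfinite(self.temperature_c)):
            raise ValueError("temperatures must be finite")

    def matric_potential(self, layers: Sequence[SoilLayerPhysical]) -> np.ndarray:
        return potential_from_theta(self.theta, layers)

    def copy(self) -> "SoilColumnState":
        return SoilColumnState(self.theta, self.temperature_c, self.drain_depth_m)


@dataclass(frozen=True)
class DailyWaterFluxes:
    """One day of field-scale water fluxes, mm."""

    precipitation_mm: float
    infiltration_mm: float
    runoff_mm: float
    drainage_mm: float
    percolation_mm: float
    aet_mm: float
    delta_storage_mm: float

    def closure_residual_mm(self) -> float:
        return self.precipitation_mm - (
            self.aet_mm + self.runoff_mm + self.drainage_mm
            + self.percolation_mm + self.delta_storage_mm
        )


# ---------------------------------------------------------------------------
# Richards step

_H_TOL = 1e-8       # m, iteration tolerance on matric potential
_MAX_ITER = 50
_MIN_SUBSTEP = 1.0 / 256.0


def _thomas(lower, diag, upper, rhs):
    """Tridiagonal solve (Thomas algorithm)."""
    n = diag.size
    c = upper.copy()
    d = rhs.copy()
    b = diag.copy()
    for i in range(1, n):
        w = lower[i - 1] / b[i - 1]
        b[i] = b[i] - w * c[i - 1]
        d[i] = d[i] - w * d[i - 1]
    x = np.empty(n)
    x[-1] = d[-1] / b[-1]
    for i in range(n - 2, -1, -1):
        x[i] = (d[i] - c[i] * x[i + 1]) / b[i]
    return x


_SPECIFIC_STORAGE = 1e-4  # m-1, compressible storage in the ponded branch
_RESID_TOL = 1e-9         # m d-1 per layer, ~1e-6 mm d-1 mass residual


def _solve_substep(theta0, layers, dz, dz_int, q_supply, sink, dt, drain_bottom):
    """One implicit sub-step. Returns (theta_new, infil, bottom_flux) in m."""
    n = len(layers)
    va, vn, vm, vtr, vts, vks = _vg_arrays(layers)
    ks = vks
    h = potential_from_theta(theta0, layers)
    theta_old = theta0.copy()
    storage_old = theta_old * dz  # initial h never ponded

    def _props(h):
        """theta, C, K, dK/dh at h from the cached vG parameter arrays."""
        neg = h < 0
        ah = va * np.abs(h)
        se = np.where(neg, (1.0 + ah**vn) ** (-vm), 1.0)
        theta = vtr + (vts - vtr) * se
        cap = np.where(
            neg,
            (vts - vtr) * va * vn * vm * ah ** (vn - 1.0) * (1.0 + ah**vn) ** (-vm - 1.0),
            0.0,
        )
        cap = np.maximum(cap, 1e-9)
        se_c = np.clip(np.minimum(se, _SE_REG), 1e-9, 1.0)
        inner = 1.0 - (1.0 - se_c ** (1.0 / vm)) ** vm
        k = _mualem_k(se, vm, vks)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_inner = (1.0 - se_c ** (1.0 / vm)) ** (vm - 1.0) * se_c ** (1.0 / vm - 1.0)
            dk_dse = vks * (0.5 / np.sqrt(se_c) * inner**2 + 2.0 * np.sqrt(se_c) * inner * d_inner)
        dk_dse = np.where(np.isfinite(dk_dse), dk_dse, 0.0)
        k_star = vks * np.sqrt(_SE_REG) * (1.0 - (1.0 - _SE_REG ** (1.0 / vm)) ** vm) ** 2
        dk_dse = np.where(se > _SE_REG, (vks - k_star) / (1.0 - _SE_REG), dk_dse)
        dk = dk_dse * np.where(neg, cap / (vts - vtr), 0.0)
        return theta, cap, k, dk

    def system(h):
        theta, cap, k, dk = _props(h)
        # ponded branch: small compressible storage keeps the system regular
        pond = np.maximum(h, 0.0)
        cap = np.where(h >= 0, _SPECIFIC_STORAGE, cap)
        storage = theta * dz + _SPECIFIC_STORAGE * pond * dz
        k_int = 0.5 * (k[:-1] + k[1:])                  # internodal, arithmetic mean
        q_cap = max(0.0, ks[0] * (-h[0] / (dz[0] / 2.0) + 1.0))
        q_top = min(q_supply, q_cap)
        q_bot = k[-1]                                   # unit-gradient free drainage
        grad = (h[:-1] - h[1:]) / dz_int
        q_internal = k_int * (grad + 1.0)
        q_in = np.empty(n)
        q_out = np.empty(n)
        q_in[0] = q_top
        q_in[1:] = q_internal
        q_out[:-1] = q_internal
        q_out[-1] = q_bot
        resid = (storage - storage_old) / dt - (q_in - q_out - sink)
        return resid, theta, k, dk, cap, k_int, grad, q_cap, q_top, q_bot

    resid, theta, k, dk, cap, k_int, grad, q_cap, q_top, q_bot = system(h)
    for _ in range(_MAX_ITER):
        # full Newton: flux derivatives include dK/dh of the vG-Mualem curve
        diag = dz * cap / dt
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        a_int = k_int / dz_int
        g1 = grad + 1.0
        # dq_internal/dh_i (upper node) and /dh_{i+1} (lower node)
        dq_dhi = a_int + 0.5 * dk[:-1] * g1
        dq_dhj = -a_int + 0.5 * dk[1:] * g1
        diag[:-1] += dq_dhi          # from q_out of layer i
        diag[1:] += -dq_dhj          # from q_in of layer i+1 (enters with -)
        upper[:] = dq_dhj            # dF_i/dh_{i+1} via q_out
        lower[:] = -dq_dhi           # dF_{i+1}/dh_i via q_in
        diag[-1] += dk[-1]           # free-drainage bottom flux
        if q_cap < q_supply and q_cap > 0.0:
            diag[0] += ks[0] / (dz[0] / 2.0)

        dh = _thomas(lower, diag, upper, -resid)
        step = np.clip(dh, -2.0, 2.0)
        # backtracking on the residual norm guards against overshoot
        norm0 = float(np.max(np.abs(resid)))
        lam = 1.0
        for _bt in range(18):
            # the storage Jacobian is discontinuous at saturation: never jump
            # across h = 0 in one move, land on the kink instead
            trial_h = h + lam * step
            crossing = (h < 0) & (trial_h > 0) | (h > 0) & (trial_h < 0)
            trial_h = np.where(crossing, 0.0, trial_h)
            trial = system(trial_h)
            if float(np.max(np.abs(trial[0]))) <= norm0 or lam < 1e-5:
                break
            lam *= 0.5
        h = trial_h
        resid, theta, k, dk, cap, k_int, grad, q_cap, q_top, q_bot = trial
        # converged when the mass residual is negligible (m d-1 per layer)
        if np.max(np.abs(resid)) < _RESID_TOL or (
            lam == 1.0 and np.max(np.abs(step)) < _H_TOL
        ):
            return theta, q_top * dt, q_bot * dt

    # Newton stalls when several nodes sit on the saturation kink; hand the
    # residual to a trust-region root finder for this substep
    sol = sp_root(lambda hh: system(hh)[0], h, method="hybr", tol=1e-12)
    resid, theta, k, dk, cap, k_int, grad, q_cap, q_top, q_bot = system(sol.x)
    if np.max(np.abs(resid)) < 1e-7:
        return theta, q_top * dt, q_bot * dt
    raise SolverError("Richards iteration did not converge")


def richards_step(
    state: SoilColumnState,
    layers: Sequence[SoilLayerPhysical],
    surface_input_mm: float,
    et_demand_by_layer_mm: np.ndarray | Sequence[float],
    dt_days: float = 1.0,
    drain_at_bottom: bool = True,
) -> tuple[SoilColumnState, DailyWaterFluxes]:
    """Advance the water profile one step.

    ``surface_input_mm`` is throughfall reaching the soil surface over the
    step; ``et_demand_by_layer_mm`` the per-layer evapotranspiration sink.
    With ``drain_at_bottom`` the unit-gradient outflow is reported as field
    drainage (captured by the drain network); otherwise as deep percolation.
    """
    if dt_days <= 0:
        raise ValueError("dt must be positive")
    if surface_input_mm < 0:
        raise ValueError("surface input must be non-negative")
    n = len(layers)
    dz = np.array([l.thickness_m for l in layers])
    dz_int = 0.5 * (dz[:-1] + dz[1:])
    tr = np.array([l.theta_r for l in layers])

    theta = state.theta.copy()
    et = np.asarray(et_demand_by_layer_mm, dtype=float) / 1000.0  # -> m
    if et.shape != (n,):
        raise ValueError("et demand must have one value per layer")
    # never let the sink pull a layer below the residual content
    et = np.minimum(et, np.maximum(0.0, (theta - tr) * dz * 0.95))
    sink_rate = et / dt_days

    q_supply = surface_input_mm / 1000.0 / dt_days
    infil = 0.0
    bottom = 0.0
    remaining = dt_days
    # infiltration fronts are steep: resolve wet steps at quarter resolution
    max_sub = dt_days / 4.0 if surface_input_mm > 0 else dt_days
    sub = max_sub
    while remaining > 1e-12:
        sub = min(sub, remaining)
        try:
            theta_new, d_inf, d_bot = _solve_substep(
                theta, layers, dz, dz_int, q_supply, sink_rate, sub, drain_at_bottom
            )
        except SolverError:
            if sub <= _MIN_SUBSTEP * dt_days:
                raise SolverError(
                    f"Richards solver failed at minimum substep; theta={theta}"
                )
            sub /= 2.0
            continue
        theta = theta_new
        infil += d_inf
        bottom += d_bot
        remaining -= sub
        sub = min(sub * 2.0, max_sub)

    aet_mm = float(et.sum() * 1000.0)
    infil_mm = infil * 1000.0
    runoff_mm = max(0.0, surface_input_mm - infil_mm)
    bottom_mm = bottom * 1000.0
    delta_storage = float(((theta - state.theta) * dz).sum() * 1000.0)
    # attribute any iteration-tolerance drift to storage bookkeeping
    drift = infil_mm - bottom_mm - aet_mm - delta_storage
    bottom_mm += drift

    fluxes = DailyWaterFluxes(
        precipitation_mm=surface_input_mm,
        infiltration_mm=infil_mm,
        runoff_mm=runoff_mm,
        drainage_mm=bottom_mm if drain_at_bottom else 0.0,
        percolation_mm=0.0 if drain_at_bottom else bottom_mm,
        aet_mm=aet_mm,
        delta_storage_mm=delta_storage,
    )
    new_state = SoilColumnState(theta, state.temperature_c, state.drain_depth_m)
    return new_state, fluxes


# ---------------------------------------------------------------------------
# Evapotranspiration

@dataclass(frozen=True)
class PotentialET:
    total_mm: float
    soil_evaporation_mm: float
    transpiration_mm: float


def _sat_vapour_pressure_kpa(t_c: float) -> float:
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def potential_evapotranspiration(
    day,
    leaf_area_index: float,
    latitude_deg: float = 50.77,
    elevation_m: float = 180.0,
) -> PotentialET:
    """FAO-56 Penman-Monteith reference evapotranspiration for one day,
    partitioned into soil evaporation and transpiration by Beer's-law canopy
    cover (extinction 0.5).

    ``day`` is any object with tmax_c, tmin_c, radiation_mj_m2, wind_m_s,
    rh_pct and date attributes. Wind speed is taken as the 2-m value.
    """
    t = 0.5 * (day.tmax_c + day.tmin_c)
    rs = day.radiation_mj_m2
    u2 = day.wind_m_s

    delta = 4098.0 * _sat_vapour_pressure_kpa(t) / (t + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    es = 0.5 * (_sat_vapour_pressure_kpa(day.tmax_c) + _sat_vapour_pressure_kpa(day.tmin_c))
    ea = day.rh_pct / 100.0 * es

    doy = day.date.timetuple().tm_yday
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(decl))))
    ra = (24.0 * 60.0 / math.pi) * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.sin(ws)
    )
    rso = (0.75 + 2e-5 * elevation_m) * ra
    rns = (1.0 - 0.23) * rs
    rel = min(1.0, max(0.3, rs / rso)) if rso > 0 else 0.3
    tmax_k, tmin_k = day.tmax_c + 273.16, day.tmin_c + 273.16
    rnl = (
        STEFAN_BOLTZMANN_MJ * 0.5 * (tmax_k**4 + tmin_k**4)
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    rn = rns - rnl

    et0 = (
        0.408 * delta * rn + gamma * 900.0 / (t + 273.0) * u2 * (es - ea)
    ) / (delta + gamma * (1.0 + 0.34 * u2))
    et0 = max(0.0, et0)

    cover = 1.0 - math.exp(-CANOPY_EXTINCTION * max(0.0, leaf_area_index))
    return PotentialET(
        total_mm=et0,
        soil_evaporation_mm=et0 * (1.0 - cover),
        transpiration_mm=et0 * cover,
    )


def actual_et(
    pet: PotentialET,
    state: SoilColumnState,
    layers: Sequence[SoilLayerPhysical],
    root_fraction: np.ndarray | Sequence[float],
) -> np.ndarray:
    """Per-layer ET extraction (mm d-1), limited by root presence and the
    water available above the wilting point.

    Transpiration from layer i is the potential transpiration weighted by
    the root fraction times a linear availability factor between wilting
    point and field capacity (no renormalization: a sparse or dry root zone
    supplies less water). Soil evaporation is drawn from the top layer.
    """
    if pet.total_mm < 0:
        raise ValueError("pet must be non-negative")
    theta = state.theta
    n = len(layers)
    rf = np.asarray(root_fraction, dtype=float)
    if rf.shape != (n,):
        raise ValueError("root fraction must have one value per layer")
    wp = np.array([l.theta_wp for l in layers])
    fc = np.array([l.theta_fc for l in layers])
    dz = np.array([l.thickness_m for l in layers])

    avail = np.clip((theta - wp) / (fc - wp), 0.0, 1.0)
    et = pet.transpiration_mm * rf * avail
    et[0] += pet.soil_evaporation_mm * avail[0]
    cap = np.maximum(0.0, (theta - wp) * dz * 1000.0)
    return np.minimum(et, cap)


# ---------------------------------------------------------------------------
# Heat conduction

def fourier_heat_step(
    state: SoilColumnState,
    layers: Sequence[SoilLayerPhysical],
    surface_temperature_c: float,
    dt_days: float = 1.0,
    substeps: int = 4,
) -> SoilColumnState:
    """Advance soil temperatures by implicit heat conduction.

    Surface boundary is Dirichlet at the forcing temperature; the lower
    boundary is insulated (zero flux).
    """
    if dt_days <= 0:
        raise ValueError("dt must be positive")
    n = len(layers)
    dz = np.array([l.thickness_m for l in layers])
    lam = np.array([l.thermal_conductivity_w_mk for l in layers]) * SECONDS_PER_DAY  # J m-1 K-1 d-1
    cv = np.array([l.heat_capacity_j_m3k for l in layers])
    t = state.temperature_c.copy()

    dz_int = 0.5 * (dz[:-1] + dz[1:])
    lam_int = 0.5 * (lam[:-1] + lam[1:])
    g_int = lam_int / dz_int              # internal conductances
    g_top = lam[0] / (dz[0] / 2.0)

    dt = dt_days / substeps
    for _ in range(substeps):
        diag = cv * dz / dt
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        rhs = cv * dz / dt * t
        diag[0] += g_top
        rhs[0] += g_top * surface_temperature_c
        diag[:-1] += g_int
        diag[1:] += g_int
        upper[:] = -g_int
        lower[:] = -g_int
        t = _thomas(lower, diag, upper, rhs)
    return SoilColumnState(state.theta, t, state.drain_depth_m)
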