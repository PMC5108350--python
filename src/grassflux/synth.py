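"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the simulator consumes can be generated here: multi-year daily
weather for a wet temperate grassland site (sinusoidal seasonal
temperatures with noise, two-state Markov precipitation occurrence with
exponential wet-day amounts, seasonal radiation coupled to wet days),
multi-member weather ensembles, complete runnable field configurations for
the three contrasting treatments, and noisy "observations" (soil moisture
by depth, daily flume water flux, cut biomass with replicate means and
standard deviations) derived from a truth simulation so that validation
statistics have a known answer.

Defaults emulate the study site's climate: mean annual precipitation near
1029 mm with maximum/minimum temperatures around 12.8/5.8 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

from .livestock import StockingPeriod
from .simulate import ManagementEvent, RunConfig, TreatmentScenario
from .soil_water import default_clay_layers
from .weather import WEATHER_COLUMNS, WeatherEnsemble, WeatherSeries

__all__ = [
    "WeatherGenParams",
    "ObservationNoise",
    "gen_weather",
    "gen_ensemble",
    "gen_observations",
    "fixture_field",
]


@dataclass(frozen=True)
class WeatherGenParams:
    """Stochastic weather generator parameters (site-level climate)."""

    tmax_mean_c: float = 12.8
    tmin_mean_c: float = 5.8
    temp_amplitude_c: float = 5.5       # seasonal half-range
    temp_noise_sd_c: float = 2.0
    p_wet_given_wet: float = 0.65
    p_wet_given_dry: float = 0.35
    annual_precip_mm: float = 1029.0    # long-run target
    radiation_mean_mj: float = 9.5
    radiation_amplitude_mj: float = 7.5
    wind_mean_m_s: float = 3.5
    rh_mean_pct: float = 82.0
    warming_offset_c: float = 0.0       # uniform shift for future time-slices

    def __post_init__(self) -> None:
        for p in (self.p_wet_given_wet, self.p_wet_given_dry):
            if not 0.0 <= p <= 1.0:
                raise ValueError("Markov probabilities must lie in [0, 1]")
        if self.temp_amplitude_c < 0 or self.radiation_amplitude_mj < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def wet_day_stationary_prob(self) -> float:
        denom = 1.0 + self.p_wet_given_dry - self.p_wet_given_wet
        return self.p_wet_given_dry / denom if denom > 0 else 0.0

    @property
    def mean_wet_day_amount_mm(self) -> float:
        pi = self.wet_day_stationary_prob
        if pi <= 0:
            return 0.0
        return self.annual_precip_mm / (365.25 * pi)


@dataclass(frozen=True)
class ObservationNoise:
    """Relative noise levels for the synthetic observation streams."""

    soil_moisture_rel_sd: float = 0.05
    flow_rel_sd: float = 0.10
    biomass_rel_sd: float = 0.10
    biomass_replicates: int = 5
    flow_floor_mm: float = 0.05        # detection floor of the flume

    def __post_init__(self) -> None:
        if min(self.soil_moisture_rel_sd, self.flow_rel_sd, self.biomass_rel_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.biomass_replicates < 2:
            raise ValueError("need at least two biomass replicates")


def gen_weather(
    params: WeatherGenParams = WeatherGenParams(),
    years: int = 1,
    start_year: int = 2001,
    seed: int | np.random.Generator = 0,
    site: str = "synthetic",
    scenario: str = "custom",
) -> WeatherSeries:
    """Generate a contiguous daily series of ``years`` calendar years."""
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dates = pd.date_range(
        Date(start_year, 1, 1), Date(start_year + years - 1, 12, 31), freq="D"
    )
    n = len(dates)
    doy = dates.day_of_year.to_numpy()
    phase = 2.0 * np.pi * (doy - 196) / 365.25        # warmest around mid-July

    tmax = (
        params.tmax_mean_c + params.warming_offset_c
        + params.temp_amplitude_c * np.cos(phase)
        + rng.normal(0.0, params.temp_noise_sd_c, n)
    )
    tmin = (
        params.tmin_mean_c + params.warming_offset_c
        + params.temp_amplitude_c * np.cos(phase)
        + rng.normal(0.0, params.temp_noise_sd_c, n)
    )
    tmin = np.minimum(tmin, tmax - 0.5)

    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    prev = rng.random() < params.wet_day_stationary_prob
    for i in range(n):
        p = params.p_wet_given_wet if prev else params.p_wet_given_dry
        wet[i] = u[i] < p
        prev = wet[i]
    amounts = rng.exponential(max(params.mean_wet_day_amount_mm, 1e-12), n)
    precip = np.where(wet, amounts, 0.0)
    if params.mean_wet_day_amount_mm == 0:
        precip[:] = 0.0

    rad = (
        params.radiation_mean_mj
        + params.radiation_amplitude_mj * np.cos(phase)
        + rng.normal(0.0, 1.5, n)
    )
    rad = np.where(wet, rad * 0.7, rad)
    rad = np.clip(rad, 0.5, None)

    wind = np.clip(rng.normal(params.wind_mean_m_s, 1.0, n), 0.2, None)
    rh = np.clip(rng.normal(params.rh_mean_pct, 6.0, n) + np.where(wet, 5.0, 0.0), 30.0, 100.0)

    df = pd.DataFrame({
        "date": dates, "tmax_c": tmax, "tmin_c": tmin, "precip_mm": precip,
        "radiation_mj_m2": rad, "wind_m_s": wind, "rh_pct": rh,
    })
    return WeatherSeries(df[WEATHER_COLUMNS], site=site, scenario=scenario)


def gen_ensemble(
    params: WeatherGenParams = WeatherGenParams(),
    years: int = 1,
    n_members: int = 20,
    seed: int = 0,
    start_year: int = 2001,
) -> WeatherEnsemble:
    """An ensemble of members differing only by sub-seed."""
    if n_members < 1:
        raise ValueError("need at least one member")
    ss = np.random.SeedSequence(seed)
    members = [
        gen_weather(params, years, start_year, np.random.default_rng(child), site="synthetic")
        for child in ss.spawn(n_members)
    ]
    return WeatherEnsemble(members)


def gen_observations(
    truth_daily: pd.DataFrame,
    noise: ObservationNoise = ObservationNoise(),
    seed: int = 0,
    moisture_every_days: int = 7,
) -> dict[str, pd.DataFrame]:
    """Derive noisy observation tables from a truth simulation.

    Returns ``soil_moisture`` (sampled dates, multiplicative noise on
    profile water content), ``flume`` (daily runoff + drainage with a
    detection floor) and ``biomass`` (per cut event: replicate mean, SD and
    SE, so 95%-confidence statistics are computable). Provenance columns
    record the underlying truth values.
    """
    rng = np.random.default_rng(seed)
    df = truth_daily

    sm = df.iloc[::moisture_every_days][["date", "theta_top", "theta_profile_mean"]].copy()
    for col in ("theta_top", "theta_profile_mean"):
        sm[f"{col}_obs"] = sm[col] * rng.normal(1.0, noise.soil_moisture_rel_sd, len(sm))
    sm = sm.rename(columns={"theta_top": "theta_top_truth",
                            "theta_profile_mean": "theta_profile_mean_truth"})

    flume_truth = (df["runoff_mm"] + df["drainage_mm"]).to_numpy()
    flume_obs = flume_truth * rng.normal(1.0, noise.flow_rel_sd, len(df))
    flume_obs = np.where(flume_obs < noise.flow_floor_mm, 0.0, flume_obs)
    flume = pd.DataFrame({
        "date": df["date"], "flux_mm_truth": flume_truth, "flux_mm_obs": flume_obs,
    })

    cuts = df[df["cut_dm_kg_ha"] > 0][["date", "cut_dm_kg_ha"]].copy()
    reps = noise.biomass_replicates
    rows = []
    for _, row in cuts.iterrows():
        samples = row["cut_dm_kg_ha"] * rng.normal(1.0, noise.biomass_rel_sd, reps)
        rows.append({
            "date": row["date"],
            "cut_dm_truth": row["cut_dm_kg_ha"],
            "cut_dm_obs_mean": samples.mean(),
            "cut_dm_obs_sd": samples.std(ddof=1),
            "cut_dm_obs_se": samples.std(ddof=1) / np.sqrt(reps),
            "replicates": reps,
        })
    biomass = pd.DataFrame(rows)
    return {"soil_moisture": sm, "flume": flume, "biomass": biomass}


def _annual_events(year: int, fert_total_kg_n: float, n_cuts: int = 2) -> list[ManagementEvent]:
    events = []
    if fert_total_kg_n > 0:
        for month in (3, 5, 7):
            events.append(ManagementEvent(
                date=Date(year, month, 15), kind="fertilizer",
                amount_kg_n_ha=fert_total_kg_n / 3.0, product="ammonium_nitrate",
            ))
    events.append(ManagementEvent(
        date=Date(year, 2, 20), kind="fym",
        fym_mass_kg_ha=10_000.0, fym_total_n_kg_ha=60.0, fym_available_n_fraction=0.25,
    ))
    cut_months = (6, 8, 9)[:n_cuts]
    for month in cut_months:
        events.append(ManagementEvent(date=Date(year, month, 5), kind="cut"))
    return events


def fixture_field(
    treatment: TreatmentScenario | str,
    years: int = 5,
    seed: int = 17,
    start_year: int = 2001,
    weather: WeatherSeries | None = None,
) -> RunConfig:
    """A complete runnable configuration for one of the three treatments on
    the shared clay-soil fixture field.

    * ``sustainable_intensification``: permanent ryegrass, full mineral N.
    * ``increased_legumes``: grass/clover sward (fixation on), reduced N.
    * ``planned_reseeding``: deep-rooting festulolium resown in year 1,
      full mineral N.
    """
    name = treatment.name if isinstance(treatment, TreatmentScenario) else treatment
    TreatmentScenario(name)  # validate
    if weather is None:
        weather = gen_weather(WeatherGenParams(), years, start_year, seed=seed)
    start = Date(start_year, 1, 1)
    end = Date(start_year + years - 1, 12, 31)

    species = {"sustainable_intensification": "ryegrass",
               "increased_legumes": "white_clover",
               "planned_reseeding": "ryegrass"}[name]
    fert = {"sustainable_intensification": 180.0,
            "increased_legumes": 90.0,
            "planned_reseeding": 180.0}[name]

    events: list[ManagementEvent] = []
    for y in range(start_year, start_year + years):
        events.extend(_annual_events(y, fert))
    if name == "planned_reseeding":
        events.append(ManagementEvent(
            date=Date(start_year, 4, 10), kind="reseed", species="festulolium",
        ))

    stocking = [
        StockingPeriod(
            start=Date(y, 5, 15), end=Date(y, 10, 1),
            head_count=30.0, field_area_ha=7.0, animal_type="beef",
        )
        for y in range(start_year, start_year + years)
    ]
    return RunConfig(
        field_label=f"fixture-{name}",
        soil_layers=default_clay_layers(),
        species=species,
        events=sorted(events, key=lambda e: e.date),
        stocking=stocking,
        weather=weather,
        start=start,
        end=end,
        seed=seed,
    )
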