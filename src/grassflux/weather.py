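"""Daily weather forcing and climate-ensemble scenario construction.

A weather-generator ensemble (many equally likely multi-decade daily series)
is collapsed into a single scenario series for simulation: every element
except precipitation is averaged across members day by day; precipitation,
whose daily distribution is strongly skewed, is instead summarized per
member as monthly totals and rain-day counts, those summaries are averaged
across members, and the mean monthly amount is then distributed randomly
over the mean number of rain days within each month.

Weather CSVs use columns
``date,tmax_c,tmin_c,precip_mm,radiation_mj_m2,wind_m_s,rh_pct``
with ISO-8601 dates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WEATHER_COLUMNS",
    "WeatherDay",
    "WeatherSeries",
    "WeatherEnsemble",
    "MonthlyPrecipSummary",
    "aggregate_ensemble",
    "summarize_precip",
    "distribute_precip",
    "read_weather_csv",
    "write_weather_csv",
]

log = logging.getLogger(__name__)

WEATHER_COLUMNS = [
    "date", "tmax_c", "tmin_c", "precip_mm", "radiation_mj_m2", "wind_m_s", "rh_pct",
]
_ELEMENT_COLUMNS = WEATHER_COLUMNS[1:]
_NON_PRECIP = [c for c in _ELEMENT_COLUMNS if c != "precip_mm"]

SCENARIO_LABELS = (
    "baseline", "2020med", "2050med", "2080med", "2020lar", "2050lar", "2080lar",
    "custom",
)

DEFAULT_WET_DAY_THRESHOLD_MM = 0.2


class WeatherValidationError(ValueError):
    pass


class EnsembleAlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class WeatherDay:
    date: Date
    tmax_c: float
    tmin_c: float
    precip_mm: float
    radiation_mj_m2: float
    wind_m_s: float
    rh_pct: float

    def __post_init__(self) -> None:
        _validate_row(self.__dict__, where=str(self.date))


def _validate_row(row: dict, where: str) -> None:
    if row["tmax_c"] < row["tmin_c"]:
        raise WeatherValidationError(f"{where}: tmax < tmin")
    if row["precip_mm"] < 0:
        raise WeatherValidationError(f"{where}: negative precipitation")
    if row["radiation_mj_m2"] < 0:
        raise WeatherValidationError(f"{where}: negative radiation")
    if not 0.0 <= row["rh_pct"] <= 100.0:
        raise WeatherValidationError(f"{where}: relative humidity outside [0, 100]")


class WeatherSeries:
    """A contiguous daily weather series backed by a pandas DataFrame."""

    def __init__(self, data: pd.DataFrame, site: str = "", scenario: str = "custom"):
        missing = [c for c in WEATHER_COLUMNS if c not in data.columns]
        if missing:
            raise WeatherValidationError(f"missing column(s): {', '.join(missing)}")
        df = data.loc[:, WEATHER_COLUMNS].reset_index(drop=True).copy()
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        deltas = df["date"].diff().dropna()
        if len(df) == 0:
            raise WeatherValidationError("empty weather series")
        if not (deltas == pd.Timedelta(days=1)).all():
            raise WeatherValidationError("dates must be strictly increasing daily with no gaps")
        for i, row in enumerate(df.itertuples(index=False)):
            d = dict(zip(WEATHER_COLUMNS, row))
            _validate_row(d, where=f"row {i} ({d['date'].date()})")
        self.data = df
        self.site = site
        self.scenario = scenario

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self):
        for row in self.data.itertuples(index=False):
            yield WeatherDay(
                date=row.date.date(), tmax_c=row.tmax_c, tmin_c=row.tmin_c,
                precip_mm=row.precip_mm, radiation_mj_m2=row.radiation_mj_m2,
                wind_m_s=row.wind_m_s, rh_pct=row.rh_pct,
            )

    def day(self, d: Date) -> WeatherDay:
        ts = pd.Timestamp(d)
        sub = self.data[self.data["date"] == ts]
        if sub.empty:
            raise KeyError(f"date {d} not in series")
        row = sub.iloc[0]
        return WeatherDay(
            date=d, tmax_c=row.tmax_c, tmin_c=row.tmin_c, precip_mm=row.precip_mm,
            radiation_mj_m2=row.radiation_mj_m2, wind_m_s=row.wind_m_s, rh_pct=row.rh_pct,
        )

    @property
    def dates(self) -> pd.Series:
        return self.data["date"]

    def annual_precip_mm(self) -> pd.Series:
        return self.data.groupby(self.data["date"].dt.year)["precip_mm"].sum()


@dataclass
class WeatherEnsemble:
    """Members of a weather-generator ensemble, all on identical dates."""

    members: list[WeatherSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise EnsembleAlignmentError("ensemble must contain at least one member")
        ref = self.members[0].dates
        for i, m in enumerate(self.members[1:], start=1):
            if len(m) != len(ref) or not (m.dates.values == ref.values).all():
                raise EnsembleAlignmentError(f"member {i} dates misaligned with member 0")

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MonthlyPrecipSummary:
    year: int
    month: int
    total_mm: float
    rain_days: float  # may be fractional when averaged across members

    def __post_init__(self) -> None:
        if self.total_mm < 0:
            raise ValueError("monthly precipitation total must be >= 0")
        ndays = pd.Period(f"{self.year}-{self.month:02d}").days_in_month
        if not 0 <= self.rain_days <= ndays:
            raise ValueError("rain days outside [0, days in month]")

    @property
    def days_in_month(self) -> int:
        return pd.Period(f"{self.year}-{self.month:02d}").days_in_month


def summarize_precip(
    series: WeatherSeries, wet_day_threshold: float = DEFAULT_WET_DAY_THRESHOLD_MM
) -> list[MonthlyPrecipSummary]:
    """Monthly precipitation totals and rain-day counts (> threshold).

    The series must cover whole calendar months.
    """
    df = series.data
    per = df["date"].dt.to_period("M")
    for p, g in df.groupby(per):
        if len(g) != p.days_in_month:
            raise WeatherValidationError(f"partial month {p}: {len(g)} of {p.days_in_month} days")
    out = []
    for p, g in df.groupby(per):
        out.append(
            MonthlyPrecipSummary(
                year=p.year, month=p.month,
                total_mm=float(g["precip_mm"].sum()),
                rain_days=float((g["precip_mm"] > wet_day_threshold).sum()),
            )
        )
    return out


def _round_half_even(x: float) -> int:
    return int(np.round(x))  # numpy rounds half to even


def distribute_precip(
    summary: MonthlyPrecipSummary,
    seed: int | np.random.Generator,
    method: str = "equal",
) -> np.ndarray:
    """Distribute a monthly total over randomly chosen wet days.

    ``round(rain_days)`` wet days (half-to-even) are drawn uniformly without
    replacement. With ``method="equal"`` the total is split equally among
    them; ``method="gamma"`` draws gamma(shape=1) weights and splits
    proportionally. If the rain-day count rounds to zero while the total is
    positive, the whole total is placed on one random day.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ndays = summary.days_in_month
    out = np.zeros(ndays)
    if summary.total_mm <= 0:
        return out
    n_wet = _round_half_even(summary.rain_days)
    if n_wet == 0:
        n_wet = 1
    wet = rng.choice(ndays, size=n_wet, replace=False)
    if method == "equal":
        out[wet] = summary.total_mm / n_wet
    elif method == "gamma":
        w = rng.gamma(1.0, 1.0, size=n_wet)
        w = w / w.sum() if w.sum() > 0 else np.full(n_wet, 1.0 / n_wet)
        out[wet] = summary.total_mm * w
    else:
        raise ValueError(f"unknown allocation method {method!r}")
    # remove float drift so the monthly sum matches exactly
    drift = summary.total_mm - out.sum()
    out[wet[0]] += drift
    return out


def aggregate_ensemble(
    ensemble: WeatherEnsemble,
    seed: int,
    wet_day_threshold: float = DEFAULT_WET_DAY_THRESHOLD_MM,
    precip_method: str = "equal",
    scenario: str = "custom",
) -> WeatherSeries:
    """Collapse an ensemble into one scenario series.

    Non-precipitation elements become per-day cross-member arithmetic means;
    monthly precipitation totals and rain-day counts are averaged across
    members and redistributed randomly within each month (seeded).
    """
    members = ensemble.members
    dates = members[0].dates.reset_index(drop=True)
    agg = pd.DataFrame({"date": dates})
    for col in _NON_PRECIP:
        agg[col] = np.mean([m.data[col].to_numpy() for m in members], axis=0)

    summaries = [summarize_precip(m, wet_day_threshold) for m in members]
    n_months = len(summaries[0])
    rng = np.random.default_rng(seed)
    precip = np.zeros(len(dates))
    per = agg["date"].dt.to_period("M")
    periods = per.drop_duplicates().tolist()
    assert len(periods) == n_months
    for j, p in enumerate(periods):
        mean_total = float(np.mean([s[j].total_mm for s in summaries]))
        mean_raindays = float(np.mean([s[j].rain_days for s in summaries]))
        merged = MonthlyPrecipSummary(p.year, p.month, mean_total, mean_raindays)
        precip[(per == p).to_numpy()] = distribute_precip(merged, rng, method=precip_method)
    agg["precip_mm"] = precip
    # clip humidity means against float drift
    agg["rh_pct"] = agg["rh_pct"].clip(0.0, 100.0)
    site = members[0].site
    return WeatherSeries(agg[WEATHER_COLUMNS], site=site, scenario=scenario)


def read_weather_csv(path: str | Path, site: str = "", scenario: str = "custom") -> WeatherSeries:
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherValidationError(
            f"{path}: missing column(s): {', '.join(missing)}"
        )
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise WeatherValidationError(f"{path}: unparsable date ({exc})") from exc
    return WeatherSeries(df, site=site, scenario=scenario)


def write_weather_csv(series: WeatherSeries, path: str | Path) -> None:
    df = series.data.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.6f")
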