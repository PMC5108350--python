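"""YAML run-configuration loading.

A run config file has blocks ``field``, ``soil``, ``species``,
``management``, ``stocking``, ``weather``, ``params`` and ``seed``; see
``examples/run_config.yaml`` for the concrete layout. The weather block
either points at a CSV (``csv: path``) or requests the synthetic generator
(``synthetic: {years: N, start_year: Y}``).
"""

from __future__ import annotations

from datetime import date as Date
from pathlib import Path

import yaml

from .livestock import StockingPeriod
from .simulate import ManagementEvent, RunConfig
from .soil_cn import CNParams
from .soil_water import SoilLayerPhysical
from .weather import read_weather_csv


def _as_date(v) -> Date:
    if isinstance(v, Date):
        return v
    return Date.fromisoformat(str(v))


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    layers = [SoilLayerPhysical(**row) for row in raw["soil"]["layers"]]
    events = [
        ManagementEvent(date=_as_date(e.pop("date")), **e)
        for e in raw.get("management", [])
    ]
    stocking = [
        StockingPeriod(start=_as_date(s.pop("start")), end=_as_date(s.pop("end")), **s)
        for s in raw.get("stocking", [])
    ]
    wblock = raw["weather"]
    if "csv" in wblock:
        weather = read_weather_csv(path.parent / wblock["csv"])
    elif "synthetic" in wblock:
        from .synth import WeatherGenParams, gen_weather

        spec = dict(wblock["synthetic"])
        years = spec.pop("years")
        start_year = spec.pop("start_year")
        weather = gen_weather(
            WeatherGenParams(**spec), years=years, start_year=start_year,
            seed=raw.get("seed", 0),
        )
    else:
        raise ValueError("weather block needs either 'csv' or 'synthetic'")

    params = CNParams(**raw.get("params", {}))
    return RunConfig(
        field_label=raw["field"]["label"],
        soil_layers=layers,
        species=raw["species"],
        events=events,
        stocking=stocking,
        weather=weather,
        start=_as_date(raw["field"]["start"]),
        end=_as_date(raw["field"]["end"]),
        seed=int(raw.get("seed", 0)),
        cn_params=params,
    )
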