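import numpy as np
import pandas as pd
import pytest

from grassflux.soil_water import SoilLayerPhysical, SoilColumnState, default_clay_layers
from grassflux.weather import WEATHER_COLUMNS, WeatherSeries


def make_weather_df(
    start="2001-01-01", days=10, tmax=12.0, tmin=6.0, precip=0.0,
    radiation=8.0, wind=3.0, rh=80.0,
):
    """A constant-valued daily weather DataFrame for targeted tests."""
    dates = pd.date_range(start, periods=days, freq="D")
    def col(v):
        return np.full(days, v, dtype=float) if np.isscalar(v) else np.asarray(v, dtype=float)
    return pd.DataFrame({
        "date": dates, "tmax_c": col(tmax), "tmin_c": col(tmin),
        "precip_mm": col(precip), "radiation_mj_m2": col(radiation),
        "wind_m_s": col(wind), "rh_pct": col(rh),
    })[WEATHER_COLUMNS]


@pytest.fixture
def weather_series_factory():
    def make(**kw):
        return WeatherSeries(make_weather_df(**kw))
    return make


@pytest.fixture
def clay_layers():
    return default_clay_layers()


@pytest.fixture
def column_at_fc(clay_layers):
    theta = np.array([l.theta_fc for l in clay_layers])
    return SoilColumnState(theta, np.full(len(clay_layers), 10.0))


@pytest.fixture
def three_layer_column():
    layers = [
        SoilLayerPhysical(0.10, 0.45, 0.35, 0.18, 0.25, vg_alpha_per_m=3.0, vg_n=1.3),
        SoilLayerPhysical(0.20, 0.47, 0.37, 0.20, 0.12, vg_alpha_per_m=3.5, vg_n=1.25),
        SoilLayerPhysical(0.30, 0.48, 0.38, 0.21, 0.06, vg_alpha_per_m=3.6, vg_n=1.22),
    ]
    theta = np.array([0.30, 0.33, 0.36])
    return layers, SoilColumnState(theta, np.full(3, 10.0))
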