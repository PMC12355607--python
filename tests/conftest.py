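import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_hourly(
    date: str,
    pollutant: str,
    values,
    station_id: str = "S01",
    unit: str = "ug/m3",
) -> pd.DataFrame:
    """One day of hourly records for one pollutant; NaN values are dropped
    (missing hours)."""
    hours = pd.date_range(date, periods=len(values), freq="h")
    df = pd.DataFrame(
        {
            "station_id": station_id,
            "datetime": hours,
            "pollutant": pollutant,
            "concentration": np.asarray(values, dtype=float),
            "unit": unit,
        }
    )
    return df.dropna(subset=["concentration"]).reset_index(drop=True)


@pytest.fixture
def hourly_builder():
    return make_hourly


@pytest.fixture
def noise_free_config():
    """Synthetic year with all randomness switched off: deterministic
    seasonal baselines only, plus the default 22-event dust calendar."""
    from aridaq.synthetic import SynthConfig, default_dust_events

    return SynthConfig(
        seed=0,
        year=2022,
        n_stations=2,
        noise_sigma=0.0,
        station_sigma=0.0,
        dust_events=default_dust_events(2022),
    )
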