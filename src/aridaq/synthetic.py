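"""Seeded synthetic inputs with the statistical structure of an arid-region
oasis city's monitoring data, so every analysis stage is testable without a
download.

What is emulated
----------------
* Winter-peaking ("U-shaped") monthly cycles for PM10, PM2.5, NO2, SO2 and
  CO and a summer-peaking ("inverted U-shaped") cycle for O3, built as a
  sinusoid on the log scale (keeps concentrations positive and gives a
  lognormal-like daily spread).
* A heating-period (Oct 10 – Apr 10) emission multiplier per pollutant,
  strongest for SO2 (coal-fired district heating).
* Dust events: rectangular hourly PM10 spikes with a configured (low)
  PM2.5/PM10 ratio, defaulting to 22 events spread over spring–autumn the
  way dust weather clusters in a desert-margin city.
* Annual indicator series following the discrete GM(1,1) restored-value
  law with known (a, u), for parameter-recovery tests.
* Monthly meteorology with configured correlation signs against pollutants
  via a single-latent-factor Gaussian construction.

One root seed drives independent sub-streams (``numpy`` ``SeedSequence``
spawn keys) per generator, so adding one generator never perturbs another.
Every generator also returns its ground truth for round-trip tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .timeseries import POLLUTANTS
from .trends import heating_label

__all__ = [
    "SynthConfig",
    "DustEvent",
    "GroundTruth",
    "default_dust_events",
    "gen_hourly_year",
    "inject_dust",
    "gen_annual_gm_series",
    "gen_met_series",
    "MET_SIGN_PATTERN",
]

_STREAMS = {"hourly": 0, "dust": 1, "gm": 2, "met": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class DustEvent:
    date: str                 # ISO date within the configured year
    start_hour: int = 10
    duration_h: int = 6
    pm10: float = 300.0       # rectangular hourly PM10 during the event
    ratio: float = 0.25       # PM2.5/PM10 during the event


def default_dust_events(year: int = 2022) -> list[DustEvent]:
    """Default dust calendar: 22 events with the spring/autumn clustering
    typical of a desert-margin city (monthly counts 1,6,6,1,1,2,4,1 over
    Mar, Apr, May, Jul, Aug, Sep, Oct, Nov)."""
    monthly = {3: 1, 4: 6, 5: 6, 7: 1, 8: 1, 9: 2, 10: 4, 11: 1}
    events = []
    for month, count in monthly.items():
        for j in range(count):
            day = 3 + 4 * j            # spread within the month
            events.append(DustEvent(date=f"{year}-{month:02d}-{day:02d}"))
    return events


#: baseline annual-mean levels (μg/m³; CO mg/m³) typical of an arid
#: northern city with coal heating
_DEFAULT_BASELINES = {
    "SO2": 7.0, "NO2": 31.0, "PM10": 70.0, "PM2.5": 42.0, "CO": 1.0, "O3": 85.0,
}
#: log-scale seasonal amplitude per pollutant
_DEFAULT_AMPLITUDES = {
    "SO2": 0.45, "NO2": 0.30, "PM10": 0.35, "PM2.5": 0.40, "CO": 0.40, "O3": 0.45,
}
#: day-of-year of the seasonal peak (mid-January for winter-peaking
#: pollutants, late June for ozone)
_DEFAULT_PEAK_DOY = {
    "SO2": 15, "NO2": 15, "PM10": 15, "PM2.5": 15, "CO": 15, "O3": 172,
}
_DEFAULT_HEATING_MULT = {
    "SO2": 2.5, "NO2": 1.6, "PM10": 1.2, "PM2.5": 1.3, "CO": 1.5, "O3": 1.0,
}


@dataclass
class SynthConfig:
    seed: int = 0
    year: int = 2022
    n_stations: int = 3
    baselines: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINES))
    seasonal_amplitude: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES))
    peak_doy: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PEAK_DOY))
    heating_multiplier: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HEATING_MULT))
    noise_sigma: float = 0.25        # lognormal hourly noise (log-SD)
    station_sigma: float = 0.08      # lognormal between-station spread
    dust_events: list[DustEvent] = field(default_factory=list)

    def __post_init__(self):
        if any(v <= 0 for v in self.baselines.values()):
            raise ValueError("baselines must be positive")
        for ev in self.dust_events:
            if not 0 < ev.ratio < 1:
                raise ValueError("dust PM2.5/PM10 ratio must lie in (0,1)")
            if pd.Timestamp(ev.date).year != self.year:
                raise ValueError(f"dust event {ev.date} outside year {self.year}")


@dataclass
class GroundTruth:
    dust_days: list[pd.Timestamp] = field(default_factory=list)
    deduction_eligible_days: list[pd.Timestamp] = field(default_factory=list)
    seasonal_peak_doy: dict[str, int] = field(default_factory=dict)
    heating_multiplier: dict[str, float] = field(default_factory=dict)
    gm_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    correlation_signs: pd.DataFrame | None = None


def _daily_level(
    config: SynthConfig, pollutant: str, dates: pd.DatetimeIndex
) -> np.ndarray:
    doy = dates.dayofyear.to_numpy()
    amp = config.seasonal_amplitude.get(pollutant, 0.0)
    peak = config.peak_doy.get(pollutant, 15)
    level = config.baselines[pollutant] * np.exp(
        amp * np.cos(2 * np.pi * (doy - peak) / 365.25)
    )
    mult = config.heating_multiplier.get(pollutant, 1.0)
    if mult != 1.0:
        heat = heating_label(dates).to_numpy()
        level = np.where(heat, level * mult, level)
    return level


def gen_hourly_year(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """One calendar year of hourly station records (long form) plus ground
    truth.  Deterministic for a fixed config (seed included)."""
    rng = _rng(config.seed, "hourly")
    dates = pd.date_range(
        f"{config.year}-01-01", f"{config.year}-12-31", freq="D"
    )
    hours = pd.date_range(
        f"{config.year}-01-01", f"{config.year + 1}-01-01",
        freq="h", inclusive="left",
    )
    station_ids = [f"S{i + 1:02d}" for i in range(config.n_stations)]
    station_factor = np.exp(
        rng.normal(0.0, config.station_sigma, size=config.n_stations)
    )
    day_index = (hours.normalize().to_numpy() - dates[0].to_datetime64()) \
        .astype("timedelta64[D]").astype(int)

    frames = []
    for pollutant in POLLUTANTS:
        daily = _daily_level(config, pollutant, dates)
        hourly_base = daily[day_index]
        for s, sid in enumerate(station_ids):
            noise = (
                np.exp(rng.normal(0.0, config.noise_sigma, size=hours.size))
                if config.noise_sigma > 0
                else np.ones(hours.size)
            )
            conc = hourly_base * station_factor[s] * noise
            frames.append(
                pd.DataFrame(
                    {
                        "station_id": sid,
                        "datetime": hours,
                        "pollutant": pollutant,
                        "concentration": conc,
                        "unit": "mg/m3" if pollutant == "CO" else "ug/m3",
                    }
                )
            )
    records = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        seasonal_peak_doy=dict(config.peak_doy),
        heating_multiplier=dict(config.heating_multiplier),
    )
    if config.dust_events:
        records, truth = inject_dust(records, config.dust_events, truth)
    return records, truth


def inject_dust(
    records: pd.DataFrame,
    events: Sequence[DustEvent],
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Overwrite PM10/PM2.5 hours with rectangular dust spikes.

    Multiple events on one date are merged (union of hours, max magnitude).
    Returns the modified records and updated ground truth.
    """
    truth = truth or GroundTruth()
    records = records.copy()
    by_date: dict[pd.Timestamp, list[DustEvent]] = {}
    for ev in events:
        by_date.setdefault(pd.Timestamp(ev.date).normalize(), []).append(ev)

    dt = records["datetime"]
    date_col = dt.dt.normalize()
    hour_col = dt.dt.hour
    for date, evs in sorted(by_date.items()):
        hours_mask = np.zeros(24, dtype=bool)
        pm10_level = np.zeros(24)
        ratio_level = np.zeros(24)
        for ev in evs:
            sel = slice(ev.start_hour, min(24, ev.start_hour + ev.duration_h))
            hours_mask[sel] = True
            idx = np.arange(24)[sel]
            take = ev.pm10 > pm10_level[idx]
            pm10_level[idx[take]] = ev.pm10
            ratio_level[idx[take]] = ev.ratio
        day_rows = (date_col == date).to_numpy()
        in_event = day_rows & hours_mask[hour_col.to_numpy()]
        pm10_rows = in_event & (records["pollutant"] == "PM10")
        pm25_rows = in_event & (records["pollutant"] == "PM2.5")
        hr10 = hour_col[pm10_rows]
        records.loc[pm10_rows, "concentration"] = pm10_level[hr10.to_numpy()]
        hr25 = hour_col[pm25_rows]
        records.loc[pm25_rows, "concentration"] = (
            pm10_level[hr25.to_numpy()] * ratio_level[hr25.to_numpy()]
        )
        truth.dust_days.append(date)
        peak = float(pm10_level.max())
        run_2h = np.any((pm10_level > 600)[1:] & (pm10_level > 600)[:-1] & hours_mask[1:] & hours_mask[:-1])
        if peak > 1000 or run_2h:
            truth.deduction_eligible_days.append(date)
    return records, truth


def gen_annual_gm_series(
    a: float,
    u: float,
    x0_1: float,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Annual series following the discrete GM(1,1) restored-value law with
    known (a, u), plus optional additive Gaussian noise."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(1.0 + 0.5 * a) < 1e-12:
        raise ValueError("a = -2 yields no restored-value law")
    x = np.empty(n)
    x[0] = x0_1
    acc = x0_1
    for k in range(1, n):
        v = (u - a * acc) / (1.0 + 0.5 * a)
        x[k] = v
        acc += v
    if noise_sd > 0:
        x = x + _rng(seed, "gm").normal(0.0, noise_sd, size=n)
    if np.any(x <= 0):
        raise ValueError("parameters yield non-positive values")
    truth = GroundTruth(gm_params={"series": (a, u)})
    return x, truth


#: correlation-sign pattern of monthly meteorology against pollutants in a
#: cold arid city: precipitation, wind, temperature and vapor pressure vary
#: against the winter-heating pollution factor (hence negative with the
#: combustion pollutants, positive with summer ozone); surface pressure and
#: relative humidity vary with it.
MET_SIGN_PATTERN = pd.DataFrame(
    {
        "SO2":   {"precipitation": -1, "pressure": 1, "wind_speed": -1,
                  "temperature": -1, "vapor_pressure": -1, "humidity": 1},
        "NO2":   {"precipitation": -1, "pressure": 1, "wind_speed": -1,
                  "temperature": -1, "vapor_pressure": -1, "humidity": 1},
        "PM10":  {"precipitation": -1, "pressure": 1, "wind_speed": -1,
                  "temperature": -1, "vapor_pressure": -1, "humidity": 1},
        "PM2.5": {"precipitation": -1, "pressure": 1, "wind_speed": -1,
                  "temperature": -1, "vapor_pressure": -1, "humidity": 1},
        "CO":    {"precipitation": -1, "pressure": 1, "wind_speed": -1,
                  "temperature": -1, "vapor_pressure": -1, "humidity": 1},
        "O3":    {"precipitation": 1, "pressure": -1, "wind_speed": 1,
                  "temperature": 1, "vapor_pressure": 1, "humidity": -1},
    }
)


def _factorize_signs(signs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Decompose sign_ji = t_j * s_i (rows = met variables, columns =
    pollutants); raises when the matrix is not rank-one representable."""
    S = signs.to_numpy(dtype=float)
    n_rows, n_cols = S.shape
    t = np.zeros(n_rows)
    s = np.zeros(n_cols)
    pivot = None
    for j in range(n_rows):
        if np.any(S[j] != 0):
            pivot = j
            break
    if pivot is None:
        return t, s
    t[pivot] = 1.0
    s = S[pivot].copy()
    for j in range(n_rows):
        row = S[j]
        if np.all(row == 0):
            continue
        nz = np.nonzero(s)[0]
        match = row[nz] / s[nz]
        if np.all(match == 1):
            t[j] = 1.0
        elif np.all(match == -1):
            t[j] = -1.0
        else:
            raise ValueError("infeasible sign matrix: not rank-one representable")
        if np.any((row != 0) & (s == 0)) or np.any((row == 0) & (s != 0)):
            raise ValueError("infeasible sign matrix: inconsistent zero pattern")
    return t, s


def gen_met_series(
    signs: pd.DataFrame | None = None,
    n_months: int = 24,
    seed: int = 0,
    strength: float = 0.8,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Monthly meteorology + pollutant table whose empirical correlation
    signs match the configured pattern in expectation.

    A single latent seasonal factor drives every variable with loading
    ±sqrt(strength) according to the factorized sign pattern, giving a
    positive-definite joint correlation by construction.  Sign matrices
    that are not expressible through one factor raise ``ValueError``.
    """
    if signs is None:
        signs = MET_SIGN_PATTERN
    if not 0 <= strength < 1:
        raise ValueError("strength must lie in [0, 1)")
    t, s = _factorize_signs(signs)
    rng = _rng(seed, "met")
    lam = np.sqrt(strength)
    factor = rng.normal(size=n_months)
    data = {}
    for j, met in enumerate(signs.index):
        eps = rng.normal(size=n_months)
        data[met] = lam * t[j] * factor + np.sqrt(1 - strength * t[j] ** 2) * eps
    for i, pol in enumerate(signs.columns):
        eps = rng.normal(size=n_months)
        data[pol] = lam * s[i] * factor + np.sqrt(1 - strength * s[i] ** 2) * eps
    table = pd.DataFrame(data)
    truth = GroundTruth(correlation_signs=signs.copy())
    return table, truth
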