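"""Hourly station data ingestion and aggregation to daily, monthly and
annual regulatory statistics.

The canonical in-memory container is a long-form :class:`pandas.DataFrame`
of hourly records with columns ``station_id, datetime, pollutant,
concentration, unit`` (concentrations in μg/m³ except CO in mg/m³; CO is
carried in mg/m³ end-to-end with no unit auto-conversion).  Timestamps are
local civil time; a day is the half-open interval [00:00, 24:00).

Validity rules follow the 24-h statistics convention: a daily mean needs at
least 20 valid hours; the daily maximum 8-h ozone mean is the maximum of the
17 windows ending 08:00–24:00, a window being valid with ≥ 6 of 8 valid
hours and the day with ≥ 14 of 17 valid windows.  Missing hours are removed,
never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POLLUTANTS = ("SO2", "NO2", "PM10", "PM2.5", "CO", "O3")
#: column name for the daily maximum 8-h rolling ozone mean
O3_8H = "O3_8h"

MIN_VALID_HOURS_DAILY = 20
MIN_VALID_HOURS_WINDOW = 6
MIN_VALID_WINDOWS_DAY = 14
N_8H_WINDOWS = 17

HOURLY_COLUMNS = ["station_id", "datetime", "pollutant", "concentration", "unit"]

__all__ = [
    "POLLUTANTS",
    "O3_8H",
    "AnnualStats",
    "read_hourly_csv",
    "aggregate_daily",
    "max_8h_mean",
    "daily_o3_8h",
    "daily_table",
    "annual_stats",
    "monthly_means",
    "nearest_rank_percentile",
]


@dataclass
class AnnualStats:
    """The six regulatory annual evaluation statistics for one year.

    Annual means for SO2/NO2/PM10/PM2.5 (μg/m³), the 95th percentile of
    CO daily means (mg/m³) and the 90th percentile of the daily maximum
    8-h O3 means (μg/m³).  A statistic is ``None`` when no valid day
    supports it.
    """

    year: int
    so2_mean: float | None = None
    no2_mean: float | None = None
    pm10_mean: float | None = None
    pm25_mean: float | None = None
    co_p95: float | None = None
    o3_8h_p90: float | None = None
    n_valid_days: int = 0
    o3_percentile: int = 90

    def as_dict(self) -> dict[str, float | None]:
        return {
            "SO2": self.so2_mean,
            "NO2": self.no2_mean,
            "PM10": self.pm10_mean,
            "PM2.5": self.pm25_mean,
            "CO": self.co_p95,
            O3_8H: self.o3_8h_p90,
        }


def read_hourly_csv(path) -> pd.DataFrame:
    """Read the hourly CSV dialect (station_id, datetime ISO-8601 local,
    pollutant, concentration, unit) into the long-form hourly frame."""
    df = pd.read_csv(path)
    missing = [c for c in HOURLY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hourly CSV missing columns: {missing}")
    df["datetime"] = pd.to_datetime(df["datetime"])
    bad = set(df["pollutant"].unique()) - set(POLLUTANTS)
    if bad:
        raise ValueError(f"unknown pollutant codes: {sorted(bad)}")
    if (df["concentration"].dropna() < 0).any():
        raise ValueError("negative concentrations in hourly input")
    return df


def _check_duplicates(records: pd.DataFrame) -> None:
    dup = records.duplicated(subset=["station_id", "datetime", "pollutant"])
    if dup.any():
        sample = records.loc[dup, ["station_id", "datetime", "pollutant"]].head(5)
        raise ValueError(
            f"{int(dup.sum())} duplicated (station, hour, pollutant) records, "
            f"e.g.\n{sample.to_string(index=False)}"
        )


def aggregate_daily(records: pd.DataFrame, scope: str = "city") -> pd.DataFrame:
    """Aggregate hourly records to daily 24-h means.

    Returns a long frame ``date, pollutant, value, n_valid_hours, day_valid``
    (plus ``station_id`` for station scope).  A station-day needs at least
    ``MIN_VALID_HOURS_DAILY`` valid hours; the city value is the unweighted
    mean over stations' valid daily values.
    """
    if scope not in ("station", "city"):
        raise ValueError(f"scope must be 'station' or 'city', got {scope!r}")
    if records.empty:
        cols = ["date", "pollutant", "value", "n_valid_hours", "day_valid"]
        if scope == "station":
            cols.insert(0, "station_id")
        return pd.DataFrame(columns=cols)
    _check_duplicates(records)

    rec = records.dropna(subset=["concentration"]).copy()
    rec["date"] = rec["datetime"].dt.normalize()
    grp = rec.groupby(["station_id", "date", "pollutant"], sort=True)["concentration"]
    daily = grp.agg(value="mean", n_valid_hours="count").reset_index()
    daily["day_valid"] = daily["n_valid_hours"] >= MIN_VALID_HOURS_DAILY
    daily.loc[~daily["day_valid"], "value"] = np.nan
    if scope == "station":
        return daily

    valid = daily[daily["day_valid"]]
    city = (
        valid.groupby(["date", "pollutant"], sort=True)["value"]
        .agg(value="mean", n_stations="count")
        .reset_index()
    )
    city["day_valid"] = city["n_stations"] >= 1
    return city


def max_8h_mean(hourly_values: Iterable[float]) -> tuple[float, int]:
    """Daily maximum 8-h rolling mean from one day's 24 hourly values
    (NaN = missing hour).

    The 17 candidate windows end 08:00–24:00; a window needs ≥ 6 valid
    hours; the day needs ≥ 14 valid windows, else ``(nan, n_valid)``.
    """
    vals = np.asarray(list(hourly_values), dtype=float)
    if vals.shape != (24,):
        raise ValueError("expected exactly 24 hourly values")
    means, n_valid = [], 0
    for start in range(N_8H_WINDOWS):
        window = vals[start : start + 8]
        ok = ~np.isnan(window)
        if ok.sum() >= MIN_VALID_HOURS_WINDOW:
            means.append(window[ok].mean())
            n_valid += 1
    if n_valid < MIN_VALID_WINDOWS_DAY:
        return math.nan, n_valid
    return float(max(means)), n_valid


def daily_o3_8h(records: pd.DataFrame, scope: str = "city") -> pd.DataFrame:
    """Daily maximum 8-h O3 means per station (or city mean over stations)."""
    o3 = records[records["pollutant"] == "O3"].copy()
    if o3.empty:
        cols = ["date", "value", "day_valid"]
        if scope == "station":
            cols.insert(0, "station_id")
        return pd.DataFrame(columns=cols)
    _check_duplicates(o3)
    o3["date"] = o3["datetime"].dt.normalize()
    o3["hour"] = o3["datetime"].dt.hour

    rows = []
    for (sid, date), day in o3.groupby(["station_id", "date"], sort=True):
        hours = np.full(24, np.nan)
        hours[day["hour"].to_numpy()] = day["concentration"].to_numpy()
        value, n_win = max_8h_mean(hours)
        rows.append(
            {
                "station_id": sid,
                "date": date,
                "value": value,
                "n_valid_windows": n_win,
                "day_valid": not math.isnan(value),
            }
        )
    per_station = pd.DataFrame(rows)
    if scope == "station":
        return per_station
    valid = per_station[per_station["day_valid"]]
    city = valid.groupby("date", sort=True)["value"].mean().reset_index()
    city["day_valid"] = True
    return city


def daily_table(records: pd.DataFrame, scope: str = "city") -> pd.DataFrame:
    """Wide daily table: index date, one column per pollutant 24-h mean plus
    the ``O3_8h`` daily maximum 8-h mean.  This is the input the AQI and
    dust accounting stages consume."""
    daily = aggregate_daily(records, scope="city" if scope == "city" else "station")
    if scope != "city":
        raise NotImplementedError("wide daily tables are produced at city scope")
    wide = daily.pivot(index="date", columns="pollutant", values="value")
    o3_8h = daily_o3_8h(records, scope="city")
    if not o3_8h.empty:
        wide[O3_8H] = o3_8h.set_index("date")["value"]
    wide.columns.name = None
    return wide.sort_index()


def nearest_rank_percentile(values: Iterable[float], p: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(p/100 × n) of the
    ascending-sorted series — always an observed value, never interpolated."""
    arr = np.sort(np.asarray([v for v in values if not math.isnan(v)], dtype=float))
    if arr.size == 0:
        raise ValueError("no valid values for percentile")
    if not 0 < p <= 100:
        raise ValueError("percentile must be in (0, 100]")
    rank = math.ceil(p / 100.0 * arr.size)
    return float(arr[rank - 1])


def annual_stats(
    daily: pd.DataFrame, year: int, o3_percentile: int = 90
) -> AnnualStats:
    """Annual regulatory statistics from the wide daily table.

    Means over valid days for SO2/NO2/PM10/PM2.5; nearest-rank 95th
    percentile of CO daily means; nearest-rank percentile (default 90th)
    of daily O3-8h maxima.  A pollutant with no valid day yields ``None``
    and a log entry.
    """
    sel = daily[daily.index.year == year]
    out = AnnualStats(year=year, o3_percentile=o3_percentile)
    out.n_valid_days = int(sel.notna().any(axis=1).sum())

    def _col(name: str) -> pd.Series:
        return sel[name].dropna() if name in sel.columns else pd.Series(dtype=float)

    for attr, name in [
        ("so2_mean", "SO2"),
        ("no2_mean", "NO2"),
        ("pm10_mean", "PM10"),
        ("pm25_mean", "PM2.5"),
    ]:
        col = _col(name)
        if col.empty:
            logger.warning("annual_stats %s: no valid days for %s", year, name)
        else:
            setattr(out, attr, float(col.mean()))
    co = _col("CO")
    if co.empty:
        logger.warning("annual_stats %s: no valid days for CO", year)
    else:
        out.co_p95 = nearest_rank_percentile(co, 95)
    o3 = _col(O3_8H)
    if o3.empty:
        logger.warning("annual_stats %s: no valid days for O3-8h", year)
    else:
        out.o3_8h_p90 = nearest_rank_percentile(o3, o3_percentile)
    return out


def monthly_means(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-month means of valid daily values (index 1..12)."""
    grouped = daily.groupby(daily.index.month).mean()
    grouped.index.name = "month"
    return grouped
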