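"""Dust-storm day screening, deduction eligibility and contribution
accounting.

A day is dust-affected when any hour has PM10 ≥ 150 μg/m³ together with a
PM2.5/PM10 ratio ≤ 0.30 (≤ 0.40 in winter, Dec–Feb) — windblown mineral
dust is coarse, so a low fine-to-coarse ratio separates dust transport from
combustion haze.  Monitoring data of a dust day may be deducted from annual
particulate statistics when the event is severe enough: hourly PM10 staying
above 600 μg/m³ for at least two consecutive hours, or above 1000 μg/m³ for
one hour.

Deduction is implemented as exclusion of flagged days from the annual PM10
mean; the contribution of dust is then the increment between the with-dust
and deducted means, and its rate the increment relative to the with-dust
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import round_half_away

__all__ = [
    "DustDayFlag",
    "DustContribution",
    "WINTER_MONTHS",
    "flag_dust_day",
    "flag_dust_days",
    "deduction_eligible",
    "dust_contribution",
    "index_contribution",
    "limit_multiple",
    "dust_day_calendar",
]

WINTER_MONTHS = frozenset({12, 1, 2})
PM10_HOURLY_TRIGGER = 150.0
RATIO_THRESHOLD = 0.30
RATIO_THRESHOLD_WINTER = 0.40
DEDUCT_2H_LEVEL = 600.0
DEDUCT_1H_LEVEL = 1000.0


@dataclass
class DustDayFlag:
    date: object
    is_dust_affected: bool
    deduction_eligible: bool
    trigger: str | None            # which screening rule fired, if any
    max_hourly_pm10: float
    min_ratio: float               # min PM2.5/PM10 over assessable hours
    assessable: bool = True        # False when no paired valid hours exist


@dataclass
class DustContribution:
    year: int
    mean_with_dust: float
    mean_deducted: float
    increment: float               # μg/m³, rounded to integer
    rate: float                    # percent of the with-dust mean, 1 decimal
    n_dust_days: int
    increment_raw: float = math.nan
    rate_raw: float = math.nan


def _ratio_threshold(date) -> float:
    month = pd.Timestamp(date).month
    return RATIO_THRESHOLD_WINTER if month in WINTER_MONTHS else RATIO_THRESHOLD


def flag_dust_day(
    pm10_hourly: Iterable[float], pm25_hourly: Iterable[float], date
) -> DustDayFlag:
    """Screen one day's paired hourly PM10/PM2.5 for dust influence.

    Ratios are computed only for hours where both values are valid and
    PM10 > 0.  Returns an unassessable flag when no such hour exists.
    """
    pm10 = np.asarray(list(pm10_hourly), dtype=float)
    pm25 = np.asarray(list(pm25_hourly), dtype=float)
    if pm10.shape != pm25.shape:
        raise ValueError("PM10 and PM2.5 hourly series differ in length")
    paired = ~np.isnan(pm10) & ~np.isnan(pm25) & (pm10 > 0)
    threshold = _ratio_threshold(date)
    if not paired.any():
        return DustDayFlag(
            date, False, False, None, math.nan, math.nan, assessable=False
        )
    ratios = pm25[paired] / pm10[paired]
    hit = (pm10[paired] >= PM10_HOURLY_TRIGGER) & (ratios <= threshold)
    affected = bool(hit.any())
    trigger = (
        f"PM10>={PM10_HOURLY_TRIGGER:g} & ratio<={threshold:g}" if affected else None
    )
    return DustDayFlag(
        date=date,
        is_dust_affected=affected,
        deduction_eligible=deduction_eligible(pm10),
        trigger=trigger,
        max_hourly_pm10=float(np.nanmax(pm10)),
        min_ratio=float(ratios.min()),
    )


def flag_dust_days(hourly: pd.DataFrame) -> list[DustDayFlag]:
    """Screen every day of a long-form hourly frame (city scope: records
    are averaged over stations per hour before screening)."""
    pm = hourly[hourly["pollutant"].isin(["PM10", "PM2.5"])].copy()
    if pm.empty:
        return []
    city = (
        pm.groupby([pm["datetime"], "pollutant"])["concentration"]
        .mean()
        .unstack("pollutant")
    )
    city["date"] = city.index.normalize()
    flags = []
    for date, day in city.groupby("date", sort=True):
        flags.append(
            flag_dust_day(
                day.get("PM10", pd.Series(dtype=float)),
                day.get("PM2.5", pd.Series(dtype=float)),
                date,
            )
        )
    return flags


def deduction_eligible(pm10_hourly: Iterable[float]) -> bool:
    """True when hourly PM10 exceeds 600 μg/m³ for ≥ 2 consecutive hours or
    1000 μg/m³ for ≥ 1 hour."""
    pm10 = np.asarray(list(pm10_hourly), dtype=float)
    if np.any(pm10 > DEDUCT_1H_LEVEL):
        return True
    above = pm10 > DEDUCT_2H_LEVEL
    return bool(np.any(above[1:] & above[:-1]))


def dust_contribution(
    daily_pm10: pd.Series, flags: Iterable[DustDayFlag], year: int | None = None
) -> DustContribution:
    """Annual PM10 increment and contribution rate attributable to dust.

    ``daily_pm10`` is a date-indexed series of valid daily means; flagged
    dust-affected days are excluded to form the deducted mean.
    """
    series = daily_pm10.dropna()
    if series.empty:
        raise ValueError("no valid daily PM10 values")
    dust_dates = {
        pd.Timestamp(f.date) for f in flags if f.is_dust_affected
    }
    keep = ~series.index.isin(dust_dates)
    if not keep.any():
        raise ValueError("every day is dust-affected; no deducted mean exists")
    mean_with = float(series.mean())
    mean_deducted = float(series[keep].mean())
    increment = mean_with - mean_deducted
    rate = increment / mean_with * 100.0
    if year is None:
        year = int(series.index[0].year)
    return DustContribution(
        year=year,
        mean_with_dust=mean_with,
        mean_deducted=mean_deducted,
        increment=round_half_away(increment, 0),
        rate=round_half_away(rate, 1),
        n_dust_days=int((~keep).sum()),
        increment_raw=increment,
        rate_raw=rate,
    )


def index_contribution(
    composite_with: float, composite_without: float
) -> tuple[float, float]:
    """Dust's contribution to the comprehensive index: the value is the
    difference of the with/without indices, the rate its percentage of the
    with-dust index (value rounded to 2 decimals, rate to 1)."""
    if composite_with <= 0:
        raise ValueError("with-dust comprehensive index must be positive")
    value = composite_with - composite_without
    rate = value / composite_with * 100.0
    return round_half_away(value, 2), round_half_away(rate, 1)


def limit_multiple(value: float, limit: float = 150.0) -> float:
    """Ratio of an observed concentration to a standard limit, one decimal
    (e.g. a 360 μg/m³ dust-day PM10 mean is 2.4 times the 150 limit)."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    return round_half_away(value / limit, 1)


def dust_day_calendar(
    flags: Iterable[DustDayFlag],
    aqi_levels: Mapping | None = None,
) -> dict:
    """Monthly dust-day counts plus, when AQI levels are supplied, the split
    of dust days that caused pollution (level ≥ 3) versus those that left
    air quality good or better."""
    monthly = {m: 0 for m in range(1, 13)}
    caused, benign, by_level = 0, 0, {}
    for f in flags:
        if not f.is_dust_affected:
            continue
        month = pd.Timestamp(f.date).month
        monthly[month] += 1
        if aqi_levels is not None:
            level = aqi_levels.get(pd.Timestamp(f.date))
            if level is None:
                continue
            by_level[level] = by_level.get(level, 0) + 1
            if level >= 3:
                caused += 1
            else:
                benign += 1
    out = {
        "monthly_counts": monthly,
        "total": sum(monthly.values()),
    }
    if aqi_levels is not None:
        out["caused_pollution_days"] = caused
        out["benign_days"] = benign
        out["by_level"] = by_level
    return out
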