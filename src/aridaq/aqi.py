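"""Individual air quality index (IAQI), daily AQI, level classification and
annual compliance tallies.

IAQI_P is the piecewise-linear transform of pollutant P's daily evaluation
statistic through the regulatory breakpoints,

    IAQI_P = (IAQI_Hi − IAQI_Lo) / (BP_Hi − BP_Lo) × (C_P − BP_Lo) + IAQI_Lo,

rounded up to an integer.  The daily AQI is the maximum of the present
IAQIs; when AQI > 50 the pollutant(s) attaining the maximum are the primary
pollutant(s).  Levels 1–6 (excellent … severe pollution) follow the AQI
bands with boundary values assigned to the lower band, so a day with
AQI ≤ 100 is a compliant ("excellent or good") day.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .config import load_breakpoints, load_levels, round_half_away
from .timeseries import O3_8H

__all__ = [
    "AQIResult",
    "AnnualAQISummary",
    "iaqi",
    "is_beyond_scale",
    "daily_aqi",
    "classify_level",
    "annual_aqi_summary",
    "season_of",
]

#: map month -> season label (northern-hemisphere meteorological seasons)
SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def season_of(date) -> str:
    return SEASONS[pd.Timestamp(date).month]


@dataclass
class AQIResult:
    """Per-day AQI outcome: IAQI vector, AQI, primary pollutant(s), level."""

    date: object
    iaqi: dict[str, int]
    aqi: int
    primary_pollutants: list[str]
    level: int
    level_label: str
    beyond_scale: list[str] = field(default_factory=list)


def is_beyond_scale(pollutant: str, concentration: float, table=None) -> bool:
    tab = (table or load_breakpoints())[pollutant]
    return concentration > tab["concentration"][-1]


def iaqi(pollutant: str, concentration: float, table=None) -> int:
    """IAQI of one pollutant's daily statistic via breakpoint interpolation.

    Exact breakpoints map to their IAQI node; interior values interpolate
    linearly and round *up* to an integer.  Concentrations above the table's
    top node are beyond the index scale and report 500.
    """
    if math.isnan(concentration):
        raise ValueError("concentration is NaN")
    if concentration < 0:
        raise ValueError(f"negative concentration for {pollutant}")
    tab = (table or load_breakpoints())[pollutant]
    conc, nodes = tab["concentration"], tab["iaqi"]
    if concentration > conc[-1]:
        return 500
    i = bisect_right(conc, concentration) - 1
    if i == len(conc) - 1:  # exactly at the top node
        return int(nodes[-1])
    lo_c, hi_c = conc[i], conc[i + 1]
    lo_n, hi_n = nodes[i], nodes[i + 1]
    value = (hi_n - lo_n) / (hi_c - lo_c) * (concentration - lo_c) + lo_n
    return int(math.ceil(value - 1e-9))


def classify_level(aqi: int) -> tuple[int, str]:
    """AQI level band 1–6; boundaries (50, 100, ...) go to the lower band."""
    if aqi < 0:
        raise ValueError("AQI must be non-negative")
    for band in load_levels():
        if band["upper"] is None or aqi <= band["upper"]:
            return band["level"], band["label"]
    raise AssertionError("unreachable")


def daily_aqi(
    concentrations: Mapping[str, float | None], date=None, table=None
) -> AQIResult:
    """Daily AQI from the day's evaluation statistics (24-h means; ozone
    enters as the ``O3_8h`` daily maximum 8-h mean).

    ``None``/NaN statistics are skipped; at least one must be present.
    Ties for the maximum IAQI report every tied pollutant as primary.
    """
    values: dict[str, int] = {}
    beyond: list[str] = []
    for pollutant, c in concentrations.items():
        if c is None or (isinstance(c, float) and math.isnan(c)):
            continue
        values[pollutant] = iaqi(pollutant, c, table=table)
        if is_beyond_scale(pollutant, c, table=table):
            beyond.append(pollutant)
    if not values:
        raise ValueError(f"no valid pollutant statistic for {date}")
    aqi_value = max(values.values())
    primary = (
        [p for p, v in values.items() if v == aqi_value] if aqi_value > 50 else []
    )
    level, label = classify_level(aqi_value)
    return AQIResult(
        date=date,
        iaqi=values,
        aqi=aqi_value,
        primary_pollutants=primary,
        level=level,
        level_label=label,
        beyond_scale=beyond,
    )


@dataclass
class AnnualAQISummary:
    n_days: int
    level_counts: dict[int, int]
    level_shares: dict[int, float]          # percent of valid days, 1 decimal
    compliance_rate: float                  # percent of level-1/2 days
    pollution_day_share: float              # percent of level >= 3 days
    season_compliance: dict[str, float]     # percent compliant per season
    season_excellent_share: dict[str, float]
    primary_pollutant_days: dict[str, int]  # days each pollutant was primary
    aqi_min: int
    aqi_max: int


def annual_aqi_summary(results: Iterable[AQIResult]) -> AnnualAQISummary:
    """Level tallies, compliance/exceedance rates, seasonal shares and
    primary-pollutant day counts over one year of valid days."""
    results = list(results)
    if not results:
        raise ValueError("no valid AQI days to summarize")
    n = len(results)
    level_counts = {lv: 0 for lv in range(1, 7)}
    season_n: dict[str, int] = {}
    season_ok: dict[str, int] = {}
    season_exc: dict[str, int] = {}
    primary_days: dict[str, int] = {}
    for r in results:
        level_counts[r.level] += 1
        if r.date is not None:
            s = season_of(r.date)
            season_n[s] = season_n.get(s, 0) + 1
            if r.level <= 2:
                season_ok[s] = season_ok.get(s, 0) + 1
            if r.level == 1:
                season_exc[s] = season_exc.get(s, 0) + 1
        for p in r.primary_pollutants:
            primary_days[p] = primary_days.get(p, 0) + 1
    shares = {
        lv: round_half_away(c / n * 100, 1) for lv, c in level_counts.items()
    }
    compliant = level_counts[1] + level_counts[2]
    return AnnualAQISummary(
        n_days=n,
        level_counts=level_counts,
        level_shares=shares,
        compliance_rate=round_half_away(compliant / n * 100, 1),
        pollution_day_share=round_half_away((n - compliant) / n * 100, 1),
        season_compliance={
            s: round_half_away(season_ok.get(s, 0) / c * 100, 1)
            for s, c in season_n.items()
        },
        season_excellent_share={
            s: round_half_away(season_exc.get(s, 0) / c * 100, 1)
            for s, c in season_n.items()
        },
        primary_pollutant_days=primary_days,
        aqi_min=min(r.aqi for r in results),
        aqi_max=max(r.aqi for r in results),
    )
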