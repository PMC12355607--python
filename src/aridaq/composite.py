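"""Ambient-air-quality comprehensive (composite) pollution index and
year-on-year comparison statistics.

The comprehensive index of a year is the sum over the six criteria
pollutants of the annual evaluation statistic divided by its Grade-II
standard limit: annual means for SO2 (60), NO2 (40), PM10 (70) and
PM2.5 (35 μg/m³); the 95th percentile of CO daily means (4 mg/m³); the
90th percentile of daily maximum 8-h O3 means (160 μg/m³).  Each ratio is a
dimensionless sub-index; an index of 6.00 means every statistic sits
exactly at its limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .config import load_limits, round_half_away
from .timeseries import AnnualStats, O3_8H

__all__ = ["CompositeIndex", "YoYChange", "composite", "yoy_change"]

STAT_KEYS = ("SO2", "NO2", "PM10", "PM2.5", "CO", O3_8H)


@dataclass
class CompositeIndex:
    year: int | None
    sub_indices: dict[str, float]
    value: float          # sum of sub-indices, two decimals
    raw_sum: float


@dataclass
class YoYChange:
    statistic: str
    current: float
    previous: float
    change_pct: float | None   # signed percent, one decimal; None if undefined
    flat: bool = False


def _as_mapping(stats) -> tuple[Mapping[str, float], int | None]:
    if isinstance(stats, AnnualStats):
        return stats.as_dict(), stats.year
    return stats, None


def composite(stats, limits: Mapping[str, float] | None = None) -> CompositeIndex:
    """Comprehensive index from the six annual statistics.

    Raises ``ValueError`` naming the pollutant if any statistic is missing.
    """
    mapping, year = _as_mapping(stats)
    limits = dict(limits or load_limits())
    subs: dict[str, float] = {}
    for key in STAT_KEYS:
        v = mapping.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing annual statistic for {key}")
        if limits[key] <= 0:
            raise ValueError(f"non-positive limit for {key}")
        subs[key] = v / limits[key]
    total = sum(subs.values())
    return CompositeIndex(
        year=year,
        sub_indices=subs,
        value=round_half_away(total, 2),
        raw_sum=total,
    )


def yoy_change(current, previous, ndigits: int = 1) -> dict[str, YoYChange]:
    """Signed percent change per statistic, (current − previous)/previous ×
    100 at one decimal (``ndigits`` configurable, e.g. 2 for the index row
    of an annual comparison table); identical values are reported flat, a
    zero previous value leaves the change undefined."""
    cur, _ = _as_mapping(current)
    prev, _ = _as_mapping(previous)
    out: dict[str, YoYChange] = {}
    for key in cur:
        if key not in prev:
            continue
        c, p = cur[key], prev[key]
        if c is None or p is None:
            continue
        if p == 0:
            out[key] = YoYChange(key, c, p, None)
            continue
        pct = round_half_away((c - p) / p * 100.0, ndigits)
        out[key] = YoYChange(key, c, p, pct, flat=(pct == 0.0))
    return out
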