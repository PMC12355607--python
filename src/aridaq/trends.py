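"""Spearman rank trend testing, correlation matrices and heating-period
split analysis.

The trend statistic for an annual indicator series of length n is

    rs = 1 − 6 Σ d_i² / (n (n² − 1)),   d_i = rank(x_i) − rank(t_i),

with average ranks for ties and time ranked 1..n.  |rs| is compared with
the two-tailed critical value W_P for n: the trend is significant when
|rs| ≥ W_P, with direction given by the sign of rs.

The heating period (coal-fired district heating in cold arid cities) runs
October 10 – April 10 inclusive; its complement is the non-heating period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import load_spearman_critical

__all__ = [
    "TrendResult",
    "CorrMatrix",
    "HeatingSplit",
    "spearman_rs",
    "critical_value",
    "trend_decision",
    "trend_test",
    "pearson_matrix",
    "heating_label",
    "heating_split",
]


@dataclass
class TrendResult:
    indicator: str | None
    n: int
    rs: float
    critical: float
    alpha: float
    significant: bool
    direction: str   # "up" | "down" | "none"


@dataclass
class CorrMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    marks: pd.DataFrame          # "" / "*" (p<0.05) / "**" (p<0.01)
    flagged: list[str]           # zero-variance variables


@dataclass
class HeatingSplit:
    labels: pd.Series            # date -> True (heating) / False
    heating: pd.Series
    non_heating: pd.Series
    r: float
    r2: float


def spearman_rs(values, times=None) -> float:
    """Rank correlation between an annual series and time order.

    Values get ascending average ranks (ties averaged); time defaults to
    1..n.  A constant series has no defined rank trend.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 periods for a rank trend")
    if np.all(x == x[0]):
        raise ValueError("constant series: rank trend undefined")
    t = np.arange(1, n + 1, dtype=float) if times is None else np.asarray(times, float)
    rx = stats.rankdata(x)
    rt = stats.rankdata(t)
    d = rx - rt
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))


def critical_value(n: int, alpha: float = 0.05) -> float:
    table = load_spearman_critical(alpha)
    if n not in table:
        raise ValueError(f"no critical value tabulated for n={n}, alpha={alpha}")
    return table[n]


def trend_decision(
    rs: float, n: int, alpha: float = 0.05, indicator: str | None = None
) -> TrendResult:
    """Significance decision for a rank trend statistic: significant iff
    |rs| ≥ W_P(n, alpha), direction from the sign of rs."""
    wp = critical_value(n, alpha)
    significant = abs(rs) >= wp
    if not significant:
        direction = "none"
    else:
        direction = "up" if rs > 0 else "down"
    return TrendResult(indicator, n, rs, wp, alpha, significant, direction)


def trend_test(values, alpha: float = 0.05, indicator: str | None = None) -> TrendResult:
    """Spearman rank trend decision for one annual indicator series."""
    return trend_decision(spearman_rs(values), len(values), alpha, indicator)


def pearson_matrix(df: pd.DataFrame) -> CorrMatrix:
    """Pairwise Pearson correlations with two-sided significance marks.

    Marks: ``**`` at p < 0.01, ``*`` at p < 0.05.  Variables with zero
    variance are flagged and their pairs left NaN.
    """
    cols = list(df.columns)
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    flagged = [c for c in cols if df[c].nunique(dropna=True) <= 1]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a in flagged or b in flagged:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            pair = df[[a, b]].dropna()
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    marks = p.map(
        lambda v: "" if (isinstance(v, float) and math.isnan(v))
        else ("**" if v < 0.01 else ("*" if v < 0.05 else ""))
    )
    np.fill_diagonal(marks.values, "")
    return CorrMatrix(r=r, p=p, marks=marks, flagged=flagged)


def heating_label(dates) -> pd.Series:
    """True for dates inside the heating period (Oct 10 – Apr 10, both
    boundary days inclusive)."""
    idx = pd.DatetimeIndex(dates)
    month, day = idx.month, idx.day
    lab = (
        (month > 10) | (month < 4)
        | ((month == 10) & (day >= 10))
        | ((month == 4) & (day <= 10))
    )
    return pd.Series(lab, index=idx)


def heating_split(daily: pd.Series) -> HeatingSplit:
    """Split a date-indexed daily series into heating / non-heating periods
    and correlate the two.

    The k-th valid day of each period is paired with the k-th of the other
    (truncated to the shorter period); the Pearson r of those paired series
    and the linear-fit R² = r² summarize how tightly the two regimes track
    each other.
    """
    series = daily.dropna().sort_index()
    lab = heating_label(series.index)
    heat = series[lab.to_numpy()]
    non = series[~lab.to_numpy()]
    if len(heat) < 3 or len(non) < 3:
        raise ValueError("each period needs at least 3 valid days")
    k = min(len(heat), len(non))
    a = heat.to_numpy()[:k]
    b = non.to_numpy()[:k]
    if np.all(a == a[0]) or np.all(b == b[0]):
        r = math.nan
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return HeatingSplit(labels=lab, heating=heat, non_heating=non, r=r, r2=r * r)
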