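"""GM(1,1) grey forecasting with posterior-variance accuracy grading.

The model treats a short positive annual series x0(1..n) as the output of a
first-order grey differential equation.  With the 1-AGO cumulative series
x1(k) = Σ_{j≤k} x0(j) and background values z1(k) = (x1(k) + x1(k−1))/2,
the development coefficient a and grey action quantity u solve the least
squares problem

    x0(k) + a·z1(k) = u,   k = 2..n.

Fitted and forecast values are restored through the same discrete grey
equation they were estimated from: given the accumulated fitted series,

    x̂0(k) = (u − a·x̂1(k−1)) / (1 + a/2),    x̂1(k) = x̂1(k−1) + x̂0(k),

with x̂0(1) = x0(1).  This restoration is exactly consistent with the
estimating equation, so a series that satisfies the grey equation (any
geometric series, ratio (1 − a/2)/(1 + a/2)) is fitted with zero residuals
and refitting on fitted values is an identity.  The continuous exponential
time response x̂1(k) = (x0(1) − u/a) e^{−a(k−1)} + u/a is available via
:func:`time_response` for reference.

Positive a means a declining series, negative a a growing one.  Model
adequacy uses the posterior-variance test: c = S2/S1 (residual SD over data
SD, population form) and the small-error probability
p = P(|e(k) − ē| < 0.6745·S1), mapped to accuracy grades 1–4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import round_half_away

__all__ = [
    "GM11Model",
    "AccuracyReport",
    "Forecast",
    "fit_gm11",
    "accuracy",
    "forecast",
    "relative_error_band",
    "time_response",
]

#: posterior-variance grade thresholds: grade -> (min p, max c); the model
#: grade is the worse of the p-grade and the c-grade.
GRADE_THRESHOLDS = {1: (0.95, 0.35), 2: (0.80, 0.50), 3: (0.70, 0.65)}
GRADE_LABELS = {1: "good", 2: "qualified", 3: "barely qualified", 4: "unqualified"}


@dataclass
class GM11Model:
    x0: np.ndarray
    x1: np.ndarray
    z1: np.ndarray
    a: float
    u: float
    fitted: np.ndarray       # x̂0(1..n), x̂0(1) = x0(1)
    residuals: np.ndarray    # e(k) = x0(k) − x̂0(k), k = 2..n

    @property
    def n(self) -> int:
        return self.x0.size


@dataclass
class AccuracyReport:
    s1: float                # population SD of the original series
    s2: float                # population SD of the residuals (k = 2..n)
    c: float                 # mean-square-error ratio S2/S1
    p: float                 # small-error probability
    grade: int               # 1 (good) .. 4 (unqualified)
    grade_label: str
    relative_errors: np.ndarray   # per-point |e|/x0 × 100, k = 2..n
    degenerate: bool = False      # constant series with nonzero residuals


@dataclass
class Forecast:
    horizon: int
    values: np.ndarray
    threshold_crossings: dict[float, int] = field(default_factory=dict)
    # threshold -> first forecast step (1-based) at/above (a<0) or at/below


def fit_gm11(x0) -> GM11Model:
    """Fit GM(1,1) to a positive series of length ≥ 4."""
    x0 = np.asarray(x0, dtype=float)
    if x0.size < 4:
        raise ValueError("GM(1,1) needs at least 4 observations")
    if np.any(x0 <= 0):
        raise ValueError("GM(1,1) requires strictly positive values")
    x1 = np.cumsum(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])          # z1(k), k = 2..n
    B = np.column_stack([-z1, np.ones_like(z1)])
    Y = x0[1:]
    sol, _, rank, _ = np.linalg.lstsq(B, Y, rcond=None)
    if rank < 2:
        raise ValueError("singular normal equations; series carries no grey signal")
    a, u = float(sol[0]), float(sol[1])
    if abs(1.0 + 0.5 * a) < 1e-12:
        raise ValueError("development coefficient a = -2; restoration undefined")
    fitted = _restore(x0[0], a, u, x0.size)
    residuals = x0[1:] - fitted[1:]
    return GM11Model(x0=x0, x1=x1, z1=z1, a=a, u=u, fitted=fitted, residuals=residuals)


def _restore(x0_1: float, a: float, u: float, n: int) -> np.ndarray:
    """Restored series from the discrete grey equation, x̂0(1) = x0(1)."""
    out = np.empty(n)
    out[0] = x0_1
    acc = x0_1
    for k in range(1, n):
        v = (u - a * acc) / (1.0 + 0.5 * a)
        out[k] = v
        acc += v
    return out


def time_response(model: GM11Model, k: int) -> float:
    """Continuous exponential time response x̂1(k) (1-based k), for
    reference alongside the discrete restoration."""
    a, u = model.a, model.u
    if a == 0:
        return model.x0[0] + u * (k - 1)
    return (model.x0[0] - u / a) * math.exp(-a * (k - 1)) + u / a


def accuracy(model: GM11Model) -> AccuracyReport:
    """Posterior-variance test of a fitted model.

    Uses population (divide-by-n) standard deviations.  A constant series
    (S1 = 0) grades as perfect when the residuals vanish too and is flagged
    degenerate otherwise.
    """
    s1 = float(np.std(model.x0))
    e = model.residuals
    s2 = float(np.std(e))
    rel = np.abs(e) / model.x0[1:] * 100.0
    if s1 == 0.0:
        # constant input: zero residuals up to floating-point noise count
        # as an exact fit
        if s2 <= 1e-10 * max(1.0, float(np.abs(model.x0).max())):
            return AccuracyReport(0.0, 0.0, 0.0, 1.0, 1, GRADE_LABELS[1], rel)
        return AccuracyReport(
            s1, s2, math.inf, 0.0, 4, GRADE_LABELS[4], rel, degenerate=True
        )
    c = s2 / s1
    p = float(np.mean(np.abs(e - e.mean()) < 0.6745 * s1))
    grade = max(_p_grade(p), _c_grade(c))
    return AccuracyReport(s1, s2, c, p, grade, GRADE_LABELS[grade], rel)


def _p_grade(p: float) -> int:
    for g, (p_min, _) in GRADE_THRESHOLDS.items():
        if p >= p_min:
            return g
    return 4


def _c_grade(c: float) -> int:
    for g, (_, c_max) in GRADE_THRESHOLDS.items():
        if c <= c_max:
            return g
    return 4


def forecast(model: GM11Model, h: int, thresholds=()) -> Forecast:
    """Extend the restored series h steps beyond the sample.

    ``thresholds`` (same units as x0) are reported with the first forecast
    step whose value crosses them — upward crossings for a growing model
    (a < 0), downward for a declining one.
    """
    if h < 1:
        raise ValueError("forecast horizon must be >= 1")
    a, u = model.a, model.u
    # continue the recursion from the accumulated fitted trajectory
    acc = float(np.sum(model.fitted))
    values = np.empty(h)
    for j in range(h):
        v = (u - a * acc) / (1.0 + 0.5 * a)
        values[j] = v
        acc += v
    crossings: dict[float, int] = {}
    for thr in thresholds:
        if a < 0:
            hit = np.nonzero(values >= thr)[0]
        else:
            hit = np.nonzero(values <= thr)[0]
        if hit.size:
            crossings[float(thr)] = int(hit[0] + 1)
    return Forecast(horizon=h, values=values, threshold_crossings=crossings)


def relative_error_band(model: GM11Model) -> tuple[float, float]:
    """(min %, max %) of the per-point relative fitting errors, k = 2..n."""
    rel = np.abs(model.residuals) / model.x0[1:] * 100.0
    return (
        round_half_away(float(rel.min()), 1),
        round_half_away(float(rel.max()), 1),
    )
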