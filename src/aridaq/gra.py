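"""Grey relational analysis: rank socio-economic driver sequences by their
geometric closeness to a reference series.

Each raw sequence is normalized to its initial image X_i'(k) = x_i(k)/x_i(1)
(so the first element is 1 and absolute scale drops out).  With difference
sequences Δ_i(k) = |x_0'(k) − x_i'(k)| and two-level extremes
m = min_i min_k Δ, M = max_i max_k Δ, the relational coefficient is

    γ_0i(k) = (m + ξ M) / (Δ_i(k) + ξ M),    ξ ∈ (0, 1),

and the relational degree γ_0i is its mean over k.  ξ (the distinguishing
coefficient) damps the distortion of a single large difference; 0.5 is the
conventional default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["GRAResult", "initial_image", "relational_degree", "rank_factors"]


@dataclass
class GRAResult:
    reference_image: np.ndarray
    images: dict[str, np.ndarray]
    deltas: dict[str, np.ndarray]
    m: float                       # two-level minimum of the differences
    M: float                       # two-level maximum of the differences
    xi: float
    coefficients: dict[str, np.ndarray]
    degrees: dict[str, float]


def initial_image(x: Sequence[float]) -> np.ndarray:
    """Normalize a sequence by its first element; the image starts at 1."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sequence")
    if arr[0] == 0:
        raise ValueError("sequence has zero first element; initial image undefined")
    if np.isnan(arr).any():
        raise ValueError("missing values are not allowed in grey sequences")
    return arr / arr[0]


def relational_degree(
    reference: Sequence[float],
    comparisons: Mapping[str, Sequence[float]],
    xi: float = 0.5,
) -> GRAResult:
    """Grey relational coefficients and degrees of each comparison sequence
    against the reference.

    All sequences must share the reference's length.  In the degenerate
    case where every comparison coincides with the reference (M = 0) all
    coefficients are defined as 1.
    """
    if not 0 < xi < 1:
        raise ValueError("distinguishing coefficient xi must lie in (0, 1)")
    if not comparisons:
        raise ValueError("need at least one comparison sequence")
    x0 = initial_image(reference)
    images: dict[str, np.ndarray] = {}
    deltas: dict[str, np.ndarray] = {}
    for name, seq in comparisons.items():
        try:
            img = initial_image(seq)
        except ValueError as err:
            raise ValueError(f"sequence {name!r}: {err}") from None
        if img.size != x0.size:
            raise ValueError(f"sequence {name!r} length differs from reference")
        images[name] = img
        deltas[name] = np.abs(x0 - img)

    all_d = np.concatenate(list(deltas.values()))
    m, M = float(all_d.min()), float(all_d.max())
    coefficients: dict[str, np.ndarray] = {}
    degrees: dict[str, float] = {}
    for name, d in deltas.items():
        if M == 0.0:
            coef = np.ones_like(d)
        else:
            coef = (m + xi * M) / (d + xi * M)
        coefficients[name] = coef
        degrees[name] = float(coef.mean())
    return GRAResult(
        reference_image=x0,
        images=images,
        deltas=deltas,
        m=m,
        M=M,
        xi=xi,
        coefficients=coefficients,
        degrees=degrees,
    )


def rank_factors(degrees: Mapping[str, float]) -> list[str]:
    """Factor names in descending order of relational degree; ties keep
    input order (stable sort)."""
    names = list(degrees)
    return sorted(names, key=lambda n: -degrees[n])
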