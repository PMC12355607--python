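"""Packaged regulatory configuration: breakpoint tables, Grade-II limits,
Spearman critical values.

Tables ship as versioned YAML under ``aridaq/data`` so a different regulatory
edition can be swapped in without touching code.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Any

import yaml

__all__ = [
    "load_breakpoints",
    "load_levels",
    "load_limits",
    "load_spearman_critical",
    "round_half_away",
]


def _load_yaml(name: str) -> dict[str, Any]:
    with resources.files("aridaq.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


@functools.lru_cache(maxsize=None)
def load_breakpoints() -> dict[str, dict[str, Any]]:
    """Return per-pollutant IAQI breakpoint tables (validated)."""
    raw = _load_yaml("breakpoints.yaml")["breakpoints"]
    for name, tab in raw.items():
        conc, nodes = tab["concentration"], tab["iaqi"]
        if len(conc) != len(nodes):
            raise ValueError(f"breakpoint table {name}: node count mismatch")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError(f"breakpoint table {name}: nodes not increasing")
    return raw


@functools.lru_cache(maxsize=None)
def load_levels() -> list[dict[str, Any]]:
    """AQI level bands (1..6) with labels and inclusive upper bounds."""
    return _load_yaml("breakpoints.yaml")["levels"]


@functools.lru_cache(maxsize=None)
def load_limits() -> dict[str, float]:
    """Grade-II evaluation limits keyed by pollutant statistic."""
    return {k: float(v) for k, v in _load_yaml("limits.yaml")["grade2_limits"].items()}


@functools.lru_cache(maxsize=None)
def load_spearman_critical(alpha: float = 0.05) -> dict[int, float]:
    """Two-tailed Spearman critical values W_P for the given alpha."""
    key = f"alpha_{alpha}"
    raw = _load_yaml("spearman_critical.yaml")
    if key not in raw:
        raise ValueError(f"no critical-value table for alpha={alpha}")
    return {int(n): float(v) for n, v in raw[key].items()}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of regulatory summaries,
    unlike banker's rounding)."""
    import math

    factor = 10.0 ** ndigits
    scaled = abs(x) * factor
    rounded = math.floor(scaled + 0.5)
    return math.copysign(rounded / factor, x)
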