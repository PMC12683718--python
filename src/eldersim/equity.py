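"""Weighted three-group Gini coefficient over subgroup mean health values.

Equity is summarized by

    G = sum_{1 <= i < j <= 3} w_i w_j |x_i - x_j|  /  ( 2 * sum_i w_i x_i )

where x_i is the mean health value of subgroup i and w_i its population
share.  G is 0 under perfect equity and bounded by 1 for non-negative inputs.
Because the numerator sums unordered pairs, G equals half the conventional
(ordered-pair) population Gini of the share-weighted pseudo-population; the
grouping identity is exercised directly by the test-suite oracle.

Subgroups are formed by each agent's INITIAL attributes, so membership is
fixed over the whole simulation; three stratifications are reported
(initial health, economic, living status) with census-share weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .population import DEFAULT_PROPORTIONS

#: Subgroup order per stratification (fixed; weights follow the same order).
DIMENSION_GROUPS: dict[str, tuple[str, str, str]] = {
    "initial_health": ("healthy", "weak", "disabled"),
    "economic": ("high", "mid", "low"),
    "living": ("with_spouse", "with_children", "alone"),
}

#: Agent attribute backing each stratification.
_DIMENSION_ATTR = {"initial_health": "initial_state", "economic": "econ", "living": "living"}

#: Census-share weights per dimension, in DIMENSION_GROUPS order.
DEFAULT_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "initial_health": (
        DEFAULT_PROPORTIONS["health"]["healthy"],
        DEFAULT_PROPORTIONS["health"]["weak"],
        DEFAULT_PROPORTIONS["health"]["disabled"],
    ),
    "economic": (
        DEFAULT_PROPORTIONS["economic"]["high"],
        DEFAULT_PROPORTIONS["economic"]["mid"],
        DEFAULT_PROPORTIONS["economic"]["low"],
    ),
    "living": (
        DEFAULT_PROPORTIONS["living"]["with_spouse"],
        DEFAULT_PROPORTIONS["living"]["with_children"],
        DEFAULT_PROPORTIONS["living"]["alone"],
    ),
}


@dataclass(frozen=True)
class StrataSpec:
    """One equity stratification: dimension name plus subgroup share weights."""

    dimension: str
    weights: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSION_GROUPS:
            raise ConfigError(f"unknown dimension {self.dimension!r}")
        w = self.resolved_weights
        if len(w) != 3 or any(wi <= 0 for wi in w):
            raise ConfigError("weights must be 3 positive shares")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError(f"weights must sum to 1, got {sum(w)}")

    @property
    def resolved_weights(self) -> tuple[float, float, float]:
        return self.weights if self.weights is not None else DEFAULT_WEIGHTS[self.dimension]

    @property
    def groups(self) -> tuple[str, str, str]:
        return DIMENSION_GROUPS[self.dimension]


@dataclass(frozen=True)
class GiniSeries:
    """Daily weighted-Gini values for one stratification."""

    dimension: str
    days: np.ndarray
    values: np.ndarray


def weighted_gini(x, w) -> float:
    """Weighted three-group Gini of subgroup means ``x`` with shares ``w``."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ConfigError("x and w must have the same length")
    if np.any(x < 0):
        raise ConfigError("subgroup means must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError(f"weights must sum to 1, got {w.sum()}")
    mean = float(w @ x)
    if mean == 0.0:
        raise DegenerateInputError("weighted Gini is undefined when all subgroup means are zero")
    num = 0.0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            num += w[i] * w[j] * abs(x[i] - x[j])
    return num / (2.0 * mean)


def subgroup_means(panel: np.ndarray, labels: list[str], groups: tuple[str, ...]) -> np.ndarray:
    """(n_days, n_groups) matrix of per-day mean H by subgroup.

    ``panel`` is an (n_days, n_agents) H matrix; ``labels`` gives each agent's
    subgroup.  Raises if any subgroup is empty.
    """
    labels_arr = np.asarray(labels)
    cols = []
    for g in groups:
        mask = labels_arr == g
        if not mask.any():
            raise ConfigError(f"subgroup {g!r} is empty; cannot compute its mean health")
        cols.append(panel[:, mask].mean(axis=1))
    return np.column_stack(cols)


def gini_timeseries(result, spec: StrataSpec, burn_in: int = 60) -> GiniSeries:
    """Daily weighted Gini over subgroup mean H, excluding burn-in days.

    ``result`` is a :class:`~eldersim.engine.SimulationResult` (or anything
    with an (n_days, n_agents) ``panel`` and a ``population`` list).  Days
    1..burn_in are excluded; day indices are 1-based.
    """
    n_days = result.panel.shape[0]
    if burn_in >= n_days:
        raise ConfigError(f"burn_in ({burn_in}) must be below simulation length ({n_days})")
    attr = _DIMENSION_ATTR[spec.dimension]
    labels = [getattr(a, attr) for a in result.population]
    means = subgroup_means(result.panel, labels, spec.groups)
    w = spec.resolved_weights
    days = np.arange(burn_in + 1, n_days + 1)
    values = np.array([weighted_gini(means[d - 1], w) for d in days])
    return GiniSeries(spec.dimension, days, values)


def gini_frame(series_by_scenario: dict[str, dict[str, GiniSeries]], replicate: int | None = None) -> pd.DataFrame:
    """Tidy frame (scenario, dimension, day, gini[, replicate]) from nested series."""
    rows = []
    for scenario, by_dim in series_by_scenario.items():
        for dim, s in by_dim.items():
            for d, v in zip(s.days, s.values):
                row = {"scenario": scenario, "dimension": dim, "day": int(d), "gini": float(v)}
                if replicate is not None:
                    row["replicate"] = replicate
                rows.append(row)
    return pd.DataFrame(rows)
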