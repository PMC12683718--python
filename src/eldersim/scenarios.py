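"""Policy scenarios: baseline S0 and four interventions as declarative overlays.

* S0 — baseline calibration.
* S1 — multi-functional community centers: 10 new comprehensive hubs with an
  elevated per-visit gain (0.05), sited greedily at the largest
  service-coverage gaps (max-min over agent homes).
* S2 — senior-friendly transportation: outing probabilities raised to
  0.8/0.7/0.4 and activity radii to 10/8/3 km (healthy/weak/disabled).
* S3 — community-based health education: no new facilities; education-host
  facilities are up-weighted (live_adjust 0.1 -> 0.2) and outing
  probabilities rise to 0.75/0.6/0.35.
* S4 — comprehensive package: rule-based parametric superposition of S1-S3;
  shared scalar parameters take the maximum, facility additions accumulate.

Scenario application is a pure overlay: the baseline parameter objects are
never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import BehaviorParams
from .environment import DistanceModel, FacilitySite
from .errors import ConfigError
from .population import DEFAULT_GAINS, Facility

#: id prefix for newly sited hubs.
_HUB_PREFIX = "H"


@dataclass(frozen=True)
class FacilityAddition:
    """New facilities an intervention adds: count, type, gain, siting rule."""

    count: int
    ftype: str = "comprehensive"
    gain: float = DEFAULT_GAINS["comprehensive"]
    education_host: bool = True
    siting: str = "coverage_gap"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigError(f"addition count must be non-negative, got {self.count}")
        if self.gain < 0:
            raise ConfigError(f"addition gain must be non-negative, got {self.gain}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Named bundle of parameter overrides and facility additions."""

    name: str
    p_out: dict[str, float] | None = None
    radius: dict[str, float] | None = None
    live_adjust: float | None = None
    additions: tuple[FacilityAddition, ...] = ()

    def __post_init__(self) -> None:
        for m, check in ((self.p_out, lambda v: 0 <= v <= 1), (self.radius, lambda v: v > 0)):
            if m is not None and not all(check(v) for v in m.values()):
                raise ConfigError(f"invalid override values in scenario {self.name}")

    def apply_behavior(self, base: BehaviorParams) -> BehaviorParams:
        """Overlay this scenario's behavioral overrides on baseline parameters."""
        kwargs = {}
        if self.p_out is not None:
            kwargs["p_out"] = {**base.p_out, **self.p_out}
        if self.radius is not None:
            kwargs["radius"] = {**base.radius, **self.radius}
        if self.live_adjust is not None:
            kwargs["live_adjust"] = self.live_adjust
        return base.evolve(**kwargs) if kwargs else base


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """The five built-in scenarios keyed by name."""
    s1 = ScenarioSpec("S1", additions=(FacilityAddition(count=10),))
    s2 = ScenarioSpec(
        "S2",
        p_out={"healthy": 0.8, "weak": 0.7, "disabled": 0.4},
        radius={"healthy": 10.0, "weak": 8.0, "disabled": 3.0},
    )
    s3 = ScenarioSpec(
        "S3",
        p_out={"healthy": 0.75, "weak": 0.6, "disabled": 0.35},
        live_adjust=0.2,
    )
    s4 = combine_scenarios([s1, s2, s3], name="S4")
    return {"S0": ScenarioSpec("S0"), "S1": s1, "S2": s2, "S3": s3, "S4": s4}


def combine_scenarios(specs: list[ScenarioSpec], name: str = "combined") -> ScenarioSpec:
    """Parametric superposition: max over shared scalars, cumulative additions."""
    if not specs:
        raise ConfigError("combine_scenarios needs at least one scenario")
    if len(specs) == 1:
        return specs[0]

    def _max_map(maps: list[dict[str, float] | None]) -> dict[str, float] | None:
        present = [m for m in maps if m is not None]
        if not present:
            return None
        keys = {k for m in present for k in m}
        return {k: max(m[k] for m in present if k in m) for k in keys}

    live = [s.live_adjust for s in specs if s.live_adjust is not None]
    additions = tuple(a for s in specs for a in s.additions)
    return ScenarioSpec(
        name=name,
        p_out=_max_map([s.p_out for s in specs]),
        radius=_max_map([s.radius for s in specs]),
        live_adjust=max(live) if live else None,
        additions=additions,
    )


def site_new_facilities(
    k: int,
    homes: np.ndarray,
    facilities: list[FacilitySite],
    dist: DistanceModel,
) -> list[FacilitySite]:
    """Greedy max-min siting of ``k`` new facilities at coverage gaps.

    Candidate locations are the agent homes.  Each round places the next site
    at the home whose distance to its nearest existing-or-new facility is
    largest (ties broken by lowest agent index); that home's gap is then
    closed and the next round re-evaluates.  Deterministic given inputs.
    """
    if k < 0:
        raise ConfigError(f"k must be non-negative, got {k}")
    homes = np.atleast_2d(np.asarray(homes, dtype=float))
    if k > 0 and len(homes) == 0:
        raise ConfigError("siting requires at least one candidate home")
    if facilities:
        locs = np.array([f.location for f in facilities])
        gap = dist.pairwise(homes, locs).min(axis=1)
    else:
        gap = np.full(len(homes), np.inf)
    new: list[FacilitySite] = []
    for i in range(k):
        best = int(gap.argmax())  # argmax takes the first (lowest index) on ties
        x, y = homes[best]
        site = FacilitySite(f"{_HUB_PREFIX}{i + 1:03d}", float(x), float(y), "comprehensive")
        new.append(site)
        d_new = dist.pairwise(homes, np.array([[x, y]]))[:, 0]
        gap = np.minimum(gap, d_new)
    return new


def realize_additions(
    spec: ScenarioSpec,
    homes: np.ndarray,
    facilities: list[Facility],
    dist: DistanceModel,
) -> list[Facility]:
    """Baseline facilities plus this scenario's newly sited ones (pure)."""
    out = list(facilities)
    n_new = 0
    for add in spec.additions:
        if add.siting != "coverage_gap":
            raise ConfigError(f"unknown siting rule {add.siting!r}")
        sites = site_new_facilities(add.count, homes, out, dist)
        out.extend(
            Facility(f"{_HUB_PREFIX}{n_new + i + 1:03d}", s.x, s.y, add.ftype, add.gain, add.education_host)
            for i, s in enumerate(sites)
        )
        n_new += len(sites)
    return out
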