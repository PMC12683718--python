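"""Daily travel behavior: outing decision, type choice, in-radius facility choice.

The decision process runs in three stages each day, keyed on the agent's
CURRENT health state (re-derived from H every day):

1. outing decision — Bernoulli with a state-specific probability
   (healthy 0.70, weak 0.50, disabled 0.30);
2. facility-type choice — categorical draw over (prevention, treatment, care)
   with state-specific preference weights;
3. facility choice — uniform-at-random among facilities of the chosen type
   within the state's activity radius (healthy 5 km, weak 3 km, disabled 1 km),
   with education-host facilities up-weighted by a factor (1 + live_adjust).
   If no facility of the demanded type is in radius, with probability 0.5 the
   agent travels to the nearest matching facility beyond the radius, otherwise
   the outing is canceled.  The agent keeps its drawn need: the fallback never
   re-draws a type.

Comprehensive hubs match every demanded type.  A visit completes within the
day; facilities have unlimited capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .environment import DistanceModel
from .errors import ConfigError
from .population import HEALTH_STATES, Facility, OlderAdult

#: Stage-1/3 type order used by the weight triples.
CHOICE_TYPES = ("prevention", "treatment", "care")

DEFAULT_P_OUT = {"healthy": 0.7, "weak": 0.5, "disabled": 0.3}
DEFAULT_RADIUS = {"healthy": 5.0, "weak": 3.0, "disabled": 1.0}
DEFAULT_TYPE_WEIGHTS = {
    "healthy": (0.6, 0.2, 0.2),
    "weak": (0.3, 0.5, 0.2),
    "disabled": (0.1, 0.3, 0.6),
}


@dataclass(frozen=True)
class BehaviorParams:
    """All behavioral parameters, defaulting to the baseline calibration."""

    p_out: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_P_OUT))
    radius: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADIUS))
    fallback_p: float = 0.5
    live_adjust: float = 0.1
    type_weights: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for s in HEALTH_STATES:
            if not 0.0 <= self.p_out[s] <= 1.0:
                raise ConfigError(f"p_out[{s}] must be in [0, 1], got {self.p_out[s]}")
            if self.radius[s] <= 0:
                raise ConfigError(f"radius[{s}] must be positive, got {self.radius[s]}")
            w = self.type_weights[s]
            if len(w) != 3 or any(wi < 0 for wi in w):
                raise ConfigError(f"type_weights[{s}] must be 3 non-negative weights")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ConfigError(f"type_weights[{s}] must sum to 1, got {sum(w)}")
        if not 0.0 <= self.fallback_p <= 1.0:
            raise ConfigError(f"fallback_p must be in [0, 1], got {self.fallback_p}")
        if self.live_adjust < 0:
            raise ConfigError(f"live_adjust must be non-negative, got {self.live_adjust}")

    def evolve(self, **kwargs) -> "BehaviorParams":
        """Return a copy with the given fields replaced (pure overlay)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class VisitEvent:
    """One completed facility visit."""

    day: int
    agent_id: int
    facility_id: str
    ftype: str
    distance_km: float
    fallback_used: bool

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ConfigError(f"day must be >= 1, got {self.day}")
        if self.distance_km < 0:
            raise ConfigError(f"distance must be non-negative, got {self.distance_km}")


def decide_outing(state: str, params: BehaviorParams, rng: np.random.Generator) -> bool:
    """Bernoulli outing decision with the state's daily outing probability."""
    return bool(rng.random() < params.p_out[state])


def choose_type(state: str, params: BehaviorParams, rng: np.random.Generator) -> str:
    """Draw the demanded facility type from the state's preference weights."""
    w = params.type_weights[state]
    u = rng.random()
    acc = 0.0
    for t, wi in zip(CHOICE_TYPES, w):
        acc += wi
        if u < acc:
            return t
    return CHOICE_TYPES[-1]


def _matches(facility: Facility, ftype: str) -> bool:
    return facility.ftype == ftype or facility.ftype == "comprehensive"


def choose_facility(
    agent: OlderAdult,
    chosen_type: str,
    facilities: list[Facility],
    dist: DistanceModel,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> Facility | None:
    """Pick a facility of the demanded type, or ``None`` if the outing is canceled.

    The in-radius pool is sampled with per-facility weight
    ``1 + live_adjust * education_host``; an empty pool triggers the
    nearest-beyond-radius fallback with probability ``fallback_p``
    (ties broken by lowest facility id).
    """
    if not facilities:
        return None
    radius = params.radius[agent.state]
    pool: list[Facility] = []
    weights: list[float] = []
    best = None  # (distance, id, facility) of nearest matching anywhere
    for f in facilities:
        if not _matches(f, chosen_type):
            continue
        d = dist.distance(agent.home, f.location)
        key = (d, f.id)
        if best is None or key < best[:2]:
            best = (d, f.id, f)
        if d <= radius:
            pool.append(f)
            weights.append(1.0 + params.live_adjust * f.education_host)
    if pool:
        total = sum(weights)
        u = rng.random() * total
        acc = 0.0
        for f, w in zip(pool, weights):
            acc += w
            if u < acc:
                return f
        return pool[-1]
    if best is None or math.isinf(best[0]):
        return None  # no matching facility reachable anywhere: outing canceled
    if rng.random() < params.fallback_p:
        return best[2]
    return None


def simulate_agent_day(
    agent: OlderAdult,
    facilities: list[Facility],
    dist: DistanceModel,
    params: BehaviorParams,
    rng: np.random.Generator,
    day: int = 1,
) -> VisitEvent | None:
    """One agent-day: outing decision -> type choice -> facility choice.

    Returns the visit event, or ``None`` when the agent stays home or the
    outing is canceled.  At most one visit per agent-day; the agent returns
    home the same day.
    """
    if not decide_outing(agent.state, params, rng):
        return None
    ftype = choose_type(agent.state, params, rng)
    facility = choose_facility(agent, ftype, facilities, dist, params, rng)
    if facility is None:
        return None
    d = dist.distance(agent.home, facility.location)
    return VisitEvent(
        day=day,
        agent_id=agent.id,
        facility_id=facility.id,
        ftype=facility.ftype,
        distance_km=d,
        fallback_used=d > params.radius[agent.state],
    )


class PoolIndex:
    """Precomputed candidate pools for fast repeated facility choice.

    For every (agent, current state, demanded type) the index stores the
    in-radius pool with cumulative selection weights plus the nearest matching
    facility overall.  Pools depend only on home locations, the facility set,
    and the radius map, all of which are fixed within a simulation run.
    """

    def __init__(
        self,
        homes: np.ndarray,
        facilities: list[Facility],
        dist: DistanceModel,
        params: BehaviorParams,
    ):
        n = len(homes)
        self.facilities = facilities
        locs = np.array([f.location for f in facilities]) if facilities else np.empty((0, 2))
        self.D = dist.pairwise(homes, locs) if facilities else np.empty((n, 0))
        self.gains = np.array([f.gain for f in facilities])
        fweights = np.array([1.0 + params.live_adjust * f.education_host for f in facilities])
        ids = [f.id for f in facilities]
        # pools[s][t][a] = (member indices, cumulative weights); nearest[s? no] per (t, a)
        self.pools: list[list[list[tuple[np.ndarray, np.ndarray]]]] = []
        self.nearest: list[list[int]] = []  # [t][a] -> facility index or -1
        for t, ftype in enumerate(CHOICE_TYPES):
            match = np.array([_matches(f, ftype) for f in facilities], dtype=bool)
            nearest_t = []
            for a in range(n):
                if match.any():
                    cand = np.flatnonzero(match)
                    # nearest matching facility, ties by lowest id
                    order = sorted(cand, key=lambda j: (self.D[a, j], ids[j]))
                    nearest_t.append(int(order[0]))
                else:
                    nearest_t.append(-1)
            self.nearest.append(nearest_t)
        for state in HEALTH_STATES:
            radius = params.radius[state]
            per_type = []
            for ftype in CHOICE_TYPES:
                match = np.array([_matches(f, ftype) for f in facilities], dtype=bool)
                per_agent = []
                for a in range(n):
                    members = np.flatnonzero(match & (self.D[a] <= radius)) if facilities else np.empty(0, int)
                    cum = np.cumsum(fweights[members]) if len(members) else np.empty(0)
                    per_agent.append((members, cum))
                per_type.append(per_agent)
            self.pools.append(per_type)
        self.fallback_p = params.fallback_p

    def draw(self, agent_idx: int, state_idx: int, type_idx: int, u: float) -> int:
        """Facility index for one outing attempt, or -1 if canceled.

        ``u`` is a single uniform variate: it selects within a non-empty pool,
        or decides the nearest-facility fallback when the pool is empty.
        """
        members, cum = self.pools[state_idx][type_idx][agent_idx]
        if len(members):
            return int(members[np.searchsorted(cum, u * cum[-1], side="right")])
        j = self.nearest[type_idx][agent_idx]
        if j >= 0 and not math.isinf(self.D[agent_idx, j]) and u < self.fallback_p:
            return j
        return -1
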