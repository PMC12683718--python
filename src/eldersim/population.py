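"""Agent and facility entities, health-state bands, stratified initialization.

Each older-adult agent carries a continuous health value H in [0, 1]
(0 = complete unhealthiness, 1 = optimal health) plus categorical living and
economic attributes.  H maps onto three categorical states via fixed bands:
healthy (H >= 0.7), weak (0.3 <= H < 0.7), disabled (H < 0.3).  The bands are
half-open at the lower edge so classification is a function; the census-style
description places the boundary value in the upper band.

Initialization is exactly stratified: attribute counts follow largest-remainder
allocation of the configured marginal proportions, and the three attribute
dimensions are assigned independently by seeded shuffles (only marginal
proportions are known; the joint distribution is an assumption, see docs).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .environment import FACILITY_TYPES, FacilitySite, StudyRegion, sample_points
from .errors import ConfigError, DomainError

HEALTH_STATES = ("healthy", "weak", "disabled")
LIVING_STATUSES = ("with_spouse", "with_children", "alone")
ECONOMIC_STATUSES = ("low", "mid", "high")

#: Band edges for H -> state classification: disabled < 0.3 <= weak < 0.7 <= healthy.
DEFAULT_THRESHOLDS = (0.3, 0.7)

#: Census-calibrated marginal proportions used to initialize the population.
DEFAULT_PROPORTIONS: dict[str, dict[str, float]] = {
    "health": {"healthy": 0.80, "weak": 0.16, "disabled": 0.04},
    "living": {"with_spouse": 0.70, "with_children": 0.29, "alone": 0.01},
    "economic": {"low": 0.69, "mid": 0.26, "high": 0.05},
}

#: Per-visit health-gain coefficients delta_type by facility type.  The
#: comprehensive value is the elevated hub gain used by the S1 intervention.
DEFAULT_GAINS = {
    "prevention": 0.001,
    "treatment": 0.003,
    "care": 0.002,
    "comprehensive": 0.05,
}

#: H band for each state: initial H is drawn uniformly within its state's band.
STATE_BANDS = {"healthy": (0.7, 1.0), "weak": (0.3, 0.7), "disabled": (0.0, 0.3)}


def classify_state(H: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Map a health value H in [0, 1] to its categorical state."""
    if not 0.0 <= H <= 1.0:
        raise DomainError(f"H must lie in [0, 1], got {H}")
    lo, hi = thresholds
    if H >= hi:
        return "healthy"
    if H >= lo:
        return "weak"
    return "disabled"


def classify_states(H: np.ndarray, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorized band classification; returns indices into HEALTH_STATES."""
    H = np.asarray(H)
    # digitize: 0 for H < lo, 1 for lo <= H < hi, 2 for H >= hi
    return 2 - np.digitize(H, thresholds)


@dataclass
class OlderAdult:
    """One agent: home location, continuous health H, fixed initial strata."""

    id: int
    home: tuple[float, float]
    H: float
    initial_state: str
    living: str
    econ: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.H <= 1.0:
            raise DomainError(f"H must lie in [0, 1], got {self.H}")
        if self.initial_state not in HEALTH_STATES:
            raise ConfigError(f"unknown health state {self.initial_state!r}")
        if self.living not in LIVING_STATUSES:
            raise ConfigError(f"unknown living status {self.living!r}")
        if self.econ not in ECONOMIC_STATUSES:
            raise ConfigError(f"unknown economic status {self.econ!r}")

    @property
    def state(self) -> str:
        """Current categorical state, always re-derived from H."""
        return classify_state(self.H)


@dataclass(frozen=True)
class Facility(FacilitySite):
    """A facility site with its per-visit health gain and education-host flag."""

    gain: float = 0.0
    education_host: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.gain < 0:
            raise ConfigError(f"gain must be non-negative, got {self.gain}")


def make_facilities(
    sites: list[FacilitySite],
    gains: dict[str, float] | None = None,
    education_host_fraction: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> list[Facility]:
    """Attach gains and education-host flags to raw sites.

    By default every prevention facility hosts community health-education
    sessions (the fraction is configurable and seeded below 1.0);
    comprehensive hubs always host them.
    """
    gains = {**DEFAULT_GAINS, **(gains or {})}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for s in sites:
        if s.ftype == "comprehensive":
            host = True
        elif s.ftype == "prevention":
            host = bool(education_host_fraction >= 1.0 or rng.random() < education_host_fraction)
        else:
            host = False
        out.append(Facility(s.id, s.x, s.y, s.ftype, gains[s.ftype], host))
    return out


def largest_remainder(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer allocation of n individuals to categories by largest remainder."""
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"proportions must sum to 1, got {total}")
    labels = list(proportions)
    quotas = np.array([n * proportions[k] for k in labels])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # ties in the fractional part break toward earlier (larger-share) labels
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(labels, (int(c) for c in counts)))


def initialize_population(
    n: int,
    proportions: dict[str, dict[str, float]] | None = None,
    region: StudyRegion | None = None,
    seed: int | np.random.Generator | None = None,
    homes: np.ndarray | None = None,
    density_weighted: bool = True,
) -> list[OlderAdult]:
    """Create ``n`` agents with exactly stratified attributes and seeded homes.

    Attribute counts per dimension follow :func:`largest_remainder`; the three
    dimensions are permuted independently so only the marginals are controlled.
    Initial H is uniform within the agent's health-state band, so the derived
    state always equals the assigned initial state.  Homes are sampled from the
    region's density surface unless an explicit (n, 2) array is given.
    """
    if n < 0:
        raise ConfigError(f"n must be non-negative, got {n}")
    props = proportions or DEFAULT_PROPORTIONS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _labels(dim: str, categories: tuple[str, ...]) -> list[str]:
        counts = largest_remainder(n, props[dim])
        labels = [c for c in categories for _ in range(counts.get(c, 0))]
        rng.shuffle(labels)
        return labels

    health = _labels("health", HEALTH_STATES)
    living = _labels("living", LIVING_STATUSES)
    econ = _labels("economic", ECONOMIC_STATUSES)

    if homes is None:
        if region is None and n > 0:
            raise ConfigError("either a region or explicit homes must be provided")
        homes = sample_points(region, n, rng, density_weighted=density_weighted) if n else np.empty((0, 2))
    homes = np.asarray(homes, dtype=float)
    if homes.shape != (n, 2):
        raise ConfigError(f"homes must be an ({n}, 2) array, got {homes.shape}")

    agents = []
    for i in range(n):
        lo, hi = STATE_BANDS[health[i]]
        agents.append(
            OlderAdult(
                id=i,
                home=(float(homes[i, 0]), float(homes[i, 1])),
                H=float(rng.uniform(lo, hi)),
                initial_state=health[i],
                living=living[i],
                econ=econ[i],
            )
        )
    return agents


def write_population_csv(agents: list[OlderAdult], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "H", "initial_state", "living", "econ"])
        for a in agents:
            w.writerow([a.id, a.home[0], a.home[1], repr(a.H), a.initial_state, a.living, a.econ])


def read_population_csv(path) -> list[OlderAdult]:
    with open(path, newline="") as fh:
        return [
            OlderAdult(
                id=int(row["id"]),
                home=(float(row["x"]), float(row["y"])),
                H=float(row["H"]),
                initial_state=row["initial_state"],
                living=row["living"],
                econ=row["econ"],
            )
            for row in csv.DictReader(fh)
        ]
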