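"""Synthetic spatial world: study region, density surface, distances, facility sites.

The simulated city is a bounded planar rectangle (local km frame, no geodesy)
with a clustered population-density surface defined as a mixture of isotropic
Gaussian kernels.  Agent homes and facility sites are both sampled from this
surface so the synthetic city reproduces the core-clustering of a dense urban
area without any external GIS input.  Distances are either straight-line
(euclidean mode, the default) or shortest paths on a perturbed grid road
network (network mode); every behavioral rule downstream depends only on the
distance function, so the two modes are interchangeable.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigError

#: The four facility types.  "comprehensive" hubs bundle all three functions.
FACILITY_TYPES = ("prevention", "treatment", "care", "comprehensive")

#: Default region: 15.5 km x 11.25 km = 174.375 km^2, the footprint of a
#: dense urban core of roughly 174 km^2.
DEFAULT_WIDTH_KM = 15.5
DEFAULT_HEIGHT_KM = 11.25


@dataclass(frozen=True)
class DensityKernel:
    """One Gaussian population cluster: centre (km), mixture weight, spread (km)."""

    x: float
    y: float
    weight: float
    spread: float


@dataclass(frozen=True)
class StudyRegion:
    """Bounded planar study region with a mixture-of-kernels density surface."""

    width: float = DEFAULT_WIDTH_KM
    height: float = DEFAULT_HEIGHT_KM
    kernels: tuple[DensityKernel, ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError(
                f"region dimensions must be positive, got {self.width} x {self.height}"
            )
        if not self.kernels:
            raise ConfigError("region needs at least one density kernel")
        for k in self.kernels:
            if k.weight <= 0:
                raise ConfigError(f"kernel weight must be positive, got {k.weight}")
            if k.spread <= 0:
                raise ConfigError(f"kernel spread must be positive, got {k.spread}")
            if not (0 <= k.x <= self.width and 0 <= k.y <= self.height):
                raise ConfigError(f"kernel centre ({k.x}, {k.y}) lies outside the region")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an (n, 2) array of points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= 0)
            & (p[:, 0] <= self.width)
            & (p[:, 1] >= 0)
            & (p[:, 1] <= self.height)
        )


@dataclass(frozen=True)
class RegionConfig:
    """Parameters for :func:`generate_region`.

    Kernel centres are drawn inside the central 80% of the rectangle so the
    density mass stays inside the region; spreads are drawn uniformly from
    ``spread_range`` (km) and mixture weights from ``weight_range`` before
    normalisation.
    """

    width: float = DEFAULT_WIDTH_KM
    height: float = DEFAULT_HEIGHT_KM
    n_kernels: int = 3
    spread_range: tuple[float, float] = (1.2, 2.5)
    weight_range: tuple[float, float] = (0.5, 1.0)


def generate_region(config: RegionConfig | None = None, seed: int | None = None) -> StudyRegion:
    """Generate a study region with seeded random density kernels."""
    config = config or RegionConfig()
    if config.width <= 0 or config.height <= 0:
        raise ConfigError(
            f"region dimensions must be positive, got {config.width} x {config.height}"
        )
    if config.n_kernels < 1:
        raise ConfigError("need at least one density kernel")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(0.1 * config.width, 0.9 * config.width, config.n_kernels)
    ys = rng.uniform(0.1 * config.height, 0.9 * config.height, config.n_kernels)
    weights = rng.uniform(*config.weight_range, config.n_kernels)
    weights = weights / weights.sum()
    spreads = rng.uniform(*config.spread_range, config.n_kernels)
    kernels = tuple(
        DensityKernel(float(x), float(y), float(w), float(s))
        for x, y, w, s in zip(xs, ys, weights, spreads)
    )
    return StudyRegion(config.width, config.height, kernels)


def sample_points(
    region: StudyRegion,
    n: int,
    seed: int | np.random.Generator | None = None,
    density_weighted: bool = True,
) -> np.ndarray:
    """Draw ``n`` locations inside the region.

    With ``density_weighted`` (default) points follow the mixture-of-kernels
    surface truncated to the rectangle (rejection sampling); otherwise they
    are uniform.  Returns an (n, 2) float array of km coordinates.
    """
    if n < 0:
        raise ConfigError(f"n must be non-negative, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 2))
    if not density_weighted:
        return np.column_stack(
            [rng.uniform(0, region.width, n), rng.uniform(0, region.height, n)]
        )
    weights = np.array([k.weight for k in region.kernels])
    weights = weights / weights.sum()
    centres = np.array([[k.x, k.y] for k in region.kernels])
    spreads = np.array([k.spread for k in region.kernels])
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(n - filled, 16)
        comp = rng.choice(len(weights), size=m, p=weights)
        pts = centres[comp] + rng.standard_normal((m, 2)) * spreads[comp, None]
        pts = pts[region.contains(pts)]
        take = min(len(pts), n - filled)
        out[filled : filled + take] = pts[:take]
        filled += take
    return out


@dataclass(frozen=True)
class FacilitySite:
    """A service site: identifier, planar location (km), and facility type."""

    id: str
    x: float
    y: float
    ftype: str

    def __post_init__(self) -> None:
        if self.ftype not in FACILITY_TYPES:
            raise ConfigError(f"unknown facility type {self.ftype!r}")

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)


_TYPE_PREFIX = {"prevention": "P", "treatment": "T", "care": "C", "comprehensive": "X"}


def generate_facilities(
    region: StudyRegion,
    counts: dict[str, int] | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[FacilitySite]:
    """Generate facility sites with density-biased locations.

    ``counts`` maps facility type to a non-negative count; the default is the
    urban service ratio of 40 prevention / 40 treatment / 20 care sites.
    """
    counts = counts if counts is not None else {"prevention": 40, "treatment": 40, "care": 20}
    for ftype, c in counts.items():
        if ftype not in FACILITY_TYPES:
            raise ConfigError(f"unknown facility type {ftype!r}")
        if c < 0:
            raise ConfigError(f"count for {ftype} must be non-negative, got {c}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites: list[FacilitySite] = []
    for ftype in FACILITY_TYPES:
        c = counts.get(ftype, 0)
        if c == 0:
            continue
        locs = sample_points(region, c, rng)
        prefix = _TYPE_PREFIX[ftype]
        sites.extend(
            FacilitySite(f"{prefix}{i + 1:03d}", float(x), float(y), ftype)
            for i, (x, y) in enumerate(locs)
        )
    return sites


class DistanceModel:
    """Distance metric between planar points: straight-line or road-network.

    In network mode each query point is snapped to its nearest graph node and
    the distance is access leg + shortest path + egress leg, which guarantees
    the network distance dominates the euclidean distance between the same
    points (graph edges carry their euclidean length or longer, and the
    triangle inequality does the rest).  Unreachable pairs return ``inf``.
    """

    def __init__(self, mode: str = "euclidean", graph: nx.Graph | None = None):
        if mode not in ("euclidean", "network"):
            raise ConfigError(f"unknown distance mode {mode!r}")
        if mode == "network":
            if graph is None or graph.number_of_nodes() == 0:
                raise ConfigError("network mode requires a non-empty graph")
            if not nx.is_connected(graph):
                raise ConfigError("network mode requires a connected graph")
        self.mode = mode
        self.graph = graph
        if graph is not None:
            self._nodes = list(graph.nodes)
            self._pos = np.array([graph.nodes[u]["pos"] for u in self._nodes], dtype=float)
            self._sp_cache: dict[int, dict] = {}

    def _snap(self, p: np.ndarray) -> np.ndarray:
        """Index of the nearest graph node for each row of an (n, 2) array."""
        d2 = ((self._pos[None, :, :] - p[:, None, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)

    def _node_dist(self, i: int, j: int) -> float:
        if i not in self._sp_cache:
            self._sp_cache[i] = nx.single_source_dijkstra_path_length(
                self.graph, self._nodes[i], weight="length"
            )
        return self._sp_cache[i].get(self._nodes[j], math.inf)

    def distance(self, a, b) -> float:
        """Distance in km between two points ``(x, y)``."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if np.array_equal(a, b):
            return 0.0
        if self.mode == "euclidean":
            return float(np.hypot(*(a - b)))
        ij = self._snap(np.vstack([a, b]))
        access = float(np.hypot(*(a - self._pos[ij[0]])))
        egress = float(np.hypot(*(b - self._pos[ij[1]])))
        return access + self._node_dist(int(ij[0]), int(ij[1])) + egress

    def pairwise(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """(len(A), len(B)) matrix of distances between two point sets."""
        A = np.atleast_2d(np.asarray(A, dtype=float))
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if self.mode == "euclidean":
            return np.hypot(
                A[:, None, 0] - B[None, :, 0], A[:, None, 1] - B[None, :, 1]
            )
        ia = self._snap(A)
        ib = self._snap(B)
        access = np.hypot(*(A - self._pos[ia]).T)
        egress = np.hypot(*(B - self._pos[ib]).T)
        D = np.empty((len(A), len(B)))
        for r, i in enumerate(ia):
            D[r] = [self._node_dist(int(i), int(j)) for j in ib]
        D += access[:, None] + egress[None, :]
        # identical points are at distance zero regardless of snapping
        same = (A[:, None, 0] == B[None, :, 0]) & (A[:, None, 1] == B[None, :, 1])
        D[same] = 0.0
        return D


def make_grid_network(
    region: StudyRegion,
    spacing: float = 0.5,
    jitter: float = 0.1,
    seed: int | None = None,
) -> nx.Graph:
    """Perturbed grid road network covering the region.

    Nodes sit on a regular lattice with the given spacing (km), displaced by
    Gaussian jitter; each 4-neighbour edge carries its euclidean length as the
    ``length`` attribute, so network distances dominate straight-line ones.
    """
    if spacing <= 0:
        raise ConfigError("grid spacing must be positive")
    rng = np.random.default_rng(seed)
    nx_cols = int(region.width // spacing) + 1
    nx_rows = int(region.height // spacing) + 1
    g = nx.Graph()
    for r in range(nx_rows):
        for c in range(nx_cols):
            x = np.clip(c * spacing + rng.normal(0, jitter * spacing), 0, region.width)
            y = np.clip(r * spacing + rng.normal(0, jitter * spacing), 0, region.height)
            g.add_node((r, c), pos=(float(x), float(y)))
    for r in range(nx_rows):
        for c in range(nx_cols):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < nx_rows and c2 < nx_cols:
                    p1 = np.array(g.nodes[(r, c)]["pos"])
                    p2 = np.array(g.nodes[(r2, c2)]["pos"])
                    g.add_edge((r, c), (r2, c2), length=float(np.hypot(*(p1 - p2))))
    return g


# ---------------------------------------------------------------------------
# Optional spatial I/O (CSV / GeoJSON facilities, CSV edge-list networks)
# ---------------------------------------------------------------------------

def write_facilities_csv(sites: list[FacilitySite], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "type"])
        for s in sites:
            w.writerow([s.id, s.x, s.y, s.ftype])


def read_facilities_csv(path) -> list[FacilitySite]:
    with open(path, newline="") as fh:
        return [
            FacilitySite(row["id"], float(row["x"]), float(row["y"]), row["type"])
            for row in csv.DictReader(fh)
        ]


def write_facilities_geojson(sites: list[FacilitySite], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.x, s.y]},
            "properties": {"id": s.id, "type": s.ftype},
        }
        for s in sites
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_facilities_geojson(path) -> list[FacilitySite]:
    with open(path) as fh:
        col = json.load(fh)
    sites = []
    for feat in col["features"]:
        x, y = feat["geometry"]["coordinates"]
        props = feat["properties"]
        sites.append(FacilitySite(str(props["id"]), float(x), float(y), props["type"]))
    return sites


def write_network_csv(graph: nx.Graph, path) -> None:
    """Edge list with node positions: u, v, length_km, ux, uy, vx, vy."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["u", "v", "length_km", "ux", "uy", "vx", "vy"])
        for u, v, data in graph.edges(data=True):
            pu, pv = graph.nodes[u]["pos"], graph.nodes[v]["pos"]
            w.writerow([u, v, data["length"], pu[0], pu[1], pv[0], pv[1]])


def read_network_csv(path) -> nx.Graph:
    g = nx.Graph()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            g.add_node(row["u"], pos=(float(row["ux"]), float(row["uy"])))
            g.add_node(row["v"], pos=(float(row["vx"]), float(row["vy"])))
            g.add_edge(row["u"], row["v"], length=float(row["length_km"]))
    return g
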