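"""Simulation orchestration: seeded runs, paired-seed experiments, sensitivity.

A run builds a synthetic world (region, facilities, agents) from a seed,
overlays a scenario, and iterates the daily cycle — state classification,
outing/type/facility decisions, health update — for ``n_days`` (default 500).
The first ``burn_in`` days (default 60) are excluded from every summary.

Experiments use a paired-seed design: within a replicate every scenario runs
on the identical environment and population (and its own behavioral RNG
stream), so scenario contrasts are within-replicate differences.  Health
changes are reported as ``delta_H`` = scenario mean H minus baseline (S0)
mean H, paired by replicate and day, which makes the baseline identically 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import CHOICE_TYPES, BehaviorParams, PoolIndex, VisitEvent
from .environment import (
    DistanceModel,
    RegionConfig,
    StudyRegion,
    generate_facilities,
    generate_region,
    make_grid_network,
)
from .equity import DIMENSION_GROUPS, GiniSeries, StrataSpec, gini_timeseries, subgroup_means
from .errors import ConfigError
from .health import HealthParams, update_health_array
from .population import (
    DEFAULT_PROPORTIONS,
    HEALTH_STATES,
    Facility,
    OlderAdult,
    classify_states,
    initialize_population,
    make_facilities,
)
from .scenarios import ScenarioSpec, builtin_scenarios, realize_additions

logger = logging.getLogger("eldersim")

DEFAULT_FACILITY_COUNTS = {"prevention": 40, "treatment": 40, "care": 20}


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable configuration of one simulation."""

    n_agents: int = 200
    n_days: int = 500
    burn_in: int = 60
    scenario: str = "S0"
    region: RegionConfig = field(default_factory=RegionConfig)
    facility_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FACILITY_COUNTS))
    proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROPORTIONS.items()}
    )
    distance_mode: str = "euclidean"
    grid_spacing: float = 0.5
    homes_density_weighted: bool = True
    education_host_fraction: float = 1.0
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    health: HealthParams = field(default_factory=HealthParams)

    def __post_init__(self) -> None:
        if self.n_agents < 0:
            raise ConfigError(f"n_agents must be non-negative, got {self.n_agents}")
        if not self.n_days > self.burn_in >= 0:
            raise ConfigError(
                f"need n_days > burn_in >= 0, got n_days={self.n_days}, burn_in={self.burn_in}"
            )
        if self.distance_mode not in ("euclidean", "network"):
            raise ConfigError(f"unknown distance mode {self.distance_mode!r}")

    def evolve(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["behavior"]["type_weights"] = {
            k: list(v) for k, v in d["behavior"]["type_weights"].items()
        }
        d["health"]["thresholds"] = list(d["health"]["thresholds"])
        d["region"]["spread_range"] = list(d["region"]["spread_range"])
        d["region"]["weight_range"] = list(d["region"]["weight_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "region" in d:
            r = dict(d["region"])
            for k in ("spread_range", "weight_range"):
                if k in r:
                    r[k] = tuple(r[k])
            d["region"] = RegionConfig(**r)
        if "behavior" in d:
            b = dict(d["behavior"])
            if "type_weights" in b:
                b["type_weights"] = {k: tuple(v) for k, v in b["type_weights"].items()}
            d["behavior"] = BehaviorParams(**b)
        if "health" in d:
            h = dict(d["health"])
            if "thresholds" in h:
                h["thresholds"] = tuple(h["thresholds"])
            d["health"] = HealthParams(**h)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})


@dataclass
class World:
    """One realized synthetic city: region, distance model, facilities, agents."""

    region: StudyRegion
    dist: DistanceModel
    facilities: list[Facility]
    agents: list[OlderAdult]

    @property
    def homes(self) -> np.ndarray:
        return np.array([a.home for a in self.agents]).reshape(len(self.agents), 2)

    def population_hash(self) -> str:
        """Stable digest of homes, initial H, and strata (paired-design check)."""
        h = hashlib.sha256()
        for a in self.agents:
            h.update(
                f"{a.id},{a.home[0]:.12f},{a.home[1]:.12f},{a.H:.12f},"
                f"{a.initial_state},{a.living},{a.econ};".encode()
            )
        return h.hexdigest()


@dataclass
class SimulationResult:
    """Per-day, per-agent outcome panel of one run plus replicate metadata."""

    config: RunConfig
    scenario: str
    seed: int
    population: list[OlderAdult]
    panel: np.ndarray  # (n_days, n_agents) end-of-day H
    visits: pd.DataFrame | None

    @property
    def mean_h(self) -> np.ndarray:
        return self.panel.mean(axis=1)

    def subgroup_mean_h(self, dimension: str) -> np.ndarray:
        attr = {"initial_health": "initial_state", "economic": "econ", "living": "living"}[dimension]
        labels = [getattr(a, attr) for a in self.population]
        return subgroup_means(self.panel, labels, DIMENSION_GROUPS[dimension])

    def gini(self, dimension: str, burn_in: int | None = None) -> GiniSeries:
        burn = self.config.burn_in if burn_in is None else burn_in
        return gini_timeseries(self, StrataSpec(dimension), burn)


def build_world(config: RunConfig, seed) -> World:
    """Generate the synthetic city for one replicate from a single seed."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_region, s_net, s_fac, s_pop = ss.spawn(4)
    region = generate_region(config.region, s_region)
    if config.distance_mode == "network":
        graph = make_grid_network(region, config.grid_spacing, seed=int(s_net.generate_state(1)[0] % 2**31))
        dist = DistanceModel("network", graph)
    else:
        dist = DistanceModel("euclidean")
    rng_fac = np.random.default_rng(s_fac)
    sites = generate_facilities(region, config.facility_counts, rng_fac)
    facilities = make_facilities(
        sites, config.health.gain, config.education_host_fraction, rng_fac
    )
    agents = initialize_population(
        config.n_agents,
        config.proportions,
        region,
        np.random.default_rng(s_pop),
        density_weighted=config.homes_density_weighted,
    )
    return World(region, dist, facilities, agents)


def _resolve_scenario(config: RunConfig, scenario) -> ScenarioSpec:
    if isinstance(scenario, ScenarioSpec):
        return scenario
    name = scenario or config.scenario
    catalog = builtin_scenarios()
    if name not in catalog:
        raise ConfigError(f"unknown scenario {name!r}; known: {sorted(catalog)}")
    return catalog[name]


def run_simulation(
    config: RunConfig,
    seed: int,
    world: World | None = None,
    scenario: str | ScenarioSpec | None = None,
    sim_seed=None,
    record_visits: bool = True,
) -> SimulationResult:
    """Run one seeded simulation and return the full outcome panel.

    ``seed`` alone drives both world generation and the behavioral stream
    (fully reproducible).  Experiments pass an explicit prebuilt ``world``
    plus a separate ``sim_seed`` for the behavioral stream so replicates stay
    paired across scenarios.
    """
    spec = _resolve_scenario(config, scenario)
    if world is None:
        ss = np.random.SeedSequence([int(seed), 0])
        world = build_world(config, ss)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 1]) if sim_seed is None else sim_seed
    )

    behavior = spec.apply_behavior(config.behavior)
    facilities = realize_additions(spec, world.homes, world.facilities, world.dist)

    n = len(world.agents)
    n_days = config.n_days
    H = np.array([a.H for a in world.agents], dtype=float)
    alone = np.array([a.living == "alone" for a in world.agents], dtype=float)
    low_econ = np.array([a.econ == "low" for a in world.agents], dtype=float)
    index = PoolIndex(world.homes, facilities, world.dist, behavior)
    p_out = np.array([behavior.p_out[s] for s in HEALTH_STATES])
    cum_w = np.cumsum([behavior.type_weights[s] for s in HEALTH_STATES], axis=1)
    radius = np.array([behavior.radius[s] for s in HEALTH_STATES])
    gains = index.gains

    panel = np.empty((n_days, n), dtype=float)
    visit_rows: list[tuple] = []
    for day in range(1, n_days + 1):
        state = classify_states(H, config.health.thresholds)
        u_out = rng.random(n)
        u_type = rng.random(n)
        u_sel = rng.random(n)
        out = u_out < p_out[state]
        t_idx = np.minimum((u_type[:, None] >= cum_w[state]).sum(axis=1), 2)
        delta = np.zeros(n)
        for a in np.flatnonzero(out):
            j = index.draw(a, int(state[a]), int(t_idx[a]), u_sel[a])
            if j < 0:
                continue
            delta[a] = gains[j]
            if record_visits:
                f = facilities[j]
                d = index.D[a, j]
                visit_rows.append(
                    (day, world.agents[a].id, f.id, f.ftype, float(d), bool(d > radius[state[a]]))
                )
        H = update_health_array(H, state, alone, low_econ, delta, config.health)
        panel[day - 1] = H

    visits = (
        pd.DataFrame(
            visit_rows,
            columns=["day", "agent_id", "facility_id", "ftype", "distance_km", "fallback_used"],
        )
        if record_visits
        else None
    )
    return SimulationResult(
        config=config,
        scenario=spec.name,
        seed=int(seed),
        population=world.agents,
        panel=panel,
        visits=visits,
    )


@dataclass
class ExperimentResult:
    """Tidy summaries of a multi-scenario, multi-replicate experiment."""

    mean_h: pd.DataFrame       # scenario, replicate, day, mean_h
    delta_h: pd.DataFrame      # scenario, replicate, day, delta_h (vs S0)
    gini: pd.DataFrame         # scenario, dimension, replicate, day, gini
    population_hashes: dict[int, str]

    @property
    def mean_h_by_day(self) -> pd.DataFrame:
        return self.mean_h.groupby(["scenario", "day"], as_index=False)["mean_h"].mean()

    @property
    def delta_h_by_day(self) -> pd.DataFrame:
        return self.delta_h.groupby(["scenario", "day"], as_index=False)["delta_h"].mean()

    @property
    def gini_by_day(self) -> pd.DataFrame:
        return self.gini.groupby(["scenario", "dimension", "day"], as_index=False)["gini"].mean()

    def final_delta(self) -> pd.DataFrame:
        """Replicate-level delta_h on the last simulated day."""
        last = self.delta_h["day"].max()
        return self.delta_h[self.delta_h["day"] == last]


def run_experiment(
    scenarios: list[str],
    replicates: int,
    base_seed: int,
    config: RunConfig | None = None,
    dimensions: tuple[str, ...] = ("initial_health", "economic", "living"),
) -> ExperimentResult:
    """Paired-seed comparison of scenarios over seeded replicates.

    Replicate ``r`` builds one world from ``(base_seed, r)`` and runs every
    scenario on it (each with its own behavioral stream), then summarizes
    mean H, delta H vs S0, and the three Gini series, excluding burn-in days.
    """
    if replicates < 1:
        raise ConfigError(f"replicates must be >= 1, got {replicates}")
    config = config or RunConfig()
    catalog = builtin_scenarios()
    specs = [_resolve_scenario(config, s) for s in scenarios]
    if "S0" not in [s.name for s in specs]:
        specs = [catalog["S0"]] + specs

    days = np.arange(config.burn_in + 1, config.n_days + 1)
    mean_rows, gini_rows = [], []
    hashes: dict[int, str] = {}
    baseline_mean: dict[int, np.ndarray] = {}
    delta_rows = []
    for r in range(replicates):
        world = build_world(config, np.random.SeedSequence([base_seed, r, 0]))
        hashes[r] = world.population_hash()
        for k, spec in enumerate(specs):
            res = run_simulation(
                config,
                base_seed,
                world=world,
                scenario=spec,
                sim_seed=np.random.SeedSequence([base_seed, r, 1 + k]),
                record_visits=False,
            )
            mh = res.mean_h[config.burn_in :]
            if spec.name == "S0":
                baseline_mean[r] = mh
            mean_rows.append(
                pd.DataFrame(
                    {"scenario": spec.name, "replicate": r, "day": days, "mean_h": mh}
                )
            )
            for dim in dimensions:
                g = res.gini(dim)
                gini_rows.append(
                    pd.DataFrame(
                        {
                            "scenario": spec.name,
                            "dimension": dim,
                            "replicate": r,
                            "day": g.days,
                            "gini": g.values,
                        }
                    )
                )
        logger.info("replicate %d/%d done", r + 1, replicates)
    mean_h = pd.concat(mean_rows, ignore_index=True)
    for (scenario, rep), grp in mean_h.groupby(["scenario", "replicate"]):
        delta_rows.append(
            pd.DataFrame(
                {
                    "scenario": scenario,
                    "replicate": rep,
                    "day": grp["day"].to_numpy(),
                    "delta_h": grp["mean_h"].to_numpy() - baseline_mean[rep],
                }
            )
        )
    return ExperimentResult(
        mean_h=mean_h,
        delta_h=pd.concat(delta_rows, ignore_index=True),
        gini=pd.concat(gini_rows, ignore_index=True),
        population_hashes=hashes,
    )


# ---------------------------------------------------------------------------
# Univariate sensitivity
# ---------------------------------------------------------------------------

def _set_decay(cfg: RunConfig, state: str, v: float) -> RunConfig:
    return cfg.evolve(health=cfg.health.evolve(decay={**cfg.health.decay, state: v}))


def _set_gain(cfg: RunConfig, ftype: str, v: float) -> RunConfig:
    return cfg.evolve(health=cfg.health.evolve(gain={**cfg.health.gain, ftype: v}))


def _set_p_out(cfg: RunConfig, state: str, v: float) -> RunConfig:
    return cfg.evolve(behavior=cfg.behavior.evolve(p_out={**cfg.behavior.p_out, state: min(v, 1.0)}))


#: name -> (baseline getter, setter); names follow the model's parameter table.
SENSITIVITY_PARAMS = {
    "healthyDecayRate": (lambda c: c.health.decay["healthy"], lambda c, v: _set_decay(c, "healthy", v)),
    "weakDecayRate": (lambda c: c.health.decay["weak"], lambda c, v: _set_decay(c, "weak", v)),
    "disabledDecayRate": (lambda c: c.health.decay["disabled"], lambda c, v: _set_decay(c, "disabled", v)),
    "aloneDecayRate": (lambda c: c.health.alone_decay, lambda c, v: c.evolve(health=c.health.evolve(alone_decay=v))),
    "lowEconomicDecay": (lambda c: c.health.low_econ_decay, lambda c, v: c.evolve(health=c.health.evolve(low_econ_decay=v))),
    "preHealthIncreaseRatio": (lambda c: c.health.gain["prevention"], lambda c, v: _set_gain(c, "prevention", v)),
    "treHealthIncreaseRatio": (lambda c: c.health.gain["treatment"], lambda c, v: _set_gain(c, "treatment", v)),
    "rehHealthIncreaseRatio": (lambda c: c.health.gain["care"], lambda c, v: _set_gain(c, "care", v)),
    "pGettingOutHealthy": (lambda c: c.behavior.p_out["healthy"], lambda c, v: _set_p_out(c, "healthy", v)),
    "fallbackP": (lambda c: c.behavior.fallback_p, lambda c, v: c.evolve(behavior=c.behavior.evolve(fallback_p=min(v, 1.0)))),
    "liveAdjust": (lambda c: c.behavior.live_adjust, lambda c, v: c.evolve(behavior=c.behavior.evolve(live_adjust=v))),
}


def univariate_sensitivity(
    param_names: list[str],
    grid: list[float],
    trials: int = 100,
    config: RunConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """One-at-a-time perturbation sweep.

    ``grid`` holds relative perturbations (0.0 is the baseline point; 0.2
    scales the parameter by 1.2).  For each (parameter, grid point) the same
    ``trials`` seeded replicate simulations are re-run with only that
    parameter changed; the table reports the across-trial mean/sd of the
    final-day population mean H and the post-burn-in time-mean H.
    """
    config = config or RunConfig()
    unknown = [p for p in param_names if p not in SENSITIVITY_PARAMS]
    if unknown:
        raise ConfigError(
            f"unknown sensitivity parameter(s) {unknown}; valid names: {sorted(SENSITIVITY_PARAMS)}"
        )
    rows = []
    for pname in param_names:
        getter, setter = SENSITIVITY_PARAMS[pname]
        base_value = getter(config)
        for rel in grid:
            value = base_value * (1.0 + rel)
            cfg = setter(config, value)
            finals, post_means = [], []
            for t in range(trials):
                world = build_world(cfg, np.random.SeedSequence([base_seed, t, 0]))
                res = run_simulation(
                    cfg,
                    base_seed,
                    world=world,
                    scenario="S0",
                    sim_seed=np.random.SeedSequence([base_seed, t, 1]),
                    record_visits=False,
                )
                finals.append(res.mean_h[-1])
                post_means.append(res.mean_h[cfg.burn_in :].mean())
            rows.append(
                {
                    "parameter": pname,
                    "perturbation": rel,
                    "value": value,
                    "trials": trials,
                    "mean_final_h": float(np.mean(finals)),
                    "sd_final_h": float(np.std(finals, ddof=1)) if trials > 1 else 0.0,
                    "mean_post_burnin_h": float(np.mean(post_means)),
                }
            )
        logger.info("sensitivity sweep for %s done", pname)
    return pd.DataFrame(rows)
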