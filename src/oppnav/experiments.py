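"""Release protocols, parameter sweeps, and robustness conditions.

A sweep runs M agents (release points equally spaced around the nest,
random initial headings) for every (gain, baseline) cell and scores the
cell by the *median* arrival distance — robust to the few agents that
get lost, unlike the mean.  Robustness conditions re-run a fixed
release protocol under single documented manipulations of the memory
acquisition, the visual resolution or the world.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .agent import AgentParams, Path, run_agent
from .angles import unit_vector
from .familiarity import FamiliarityContext, calibrate_average_world_familiarity
from .memory import LearningWalkSpec, MemoryBank, RouteSpec, build_memory_banks
from .world import ViewGeometry, WorldModel, generate_world

#: Condition names and the single override set each one applies.
CONDITION_NAMES = (
    "baseline_default",
    "decoupled",
    "noisy_learning_90",
    "half_memories_10",
    "coarse_resolution_10deg",
    "small_learning_walk_10cm",
    "cluttered_world",
    "unfamiliar_release",
)


def _derive_seed(*keys: int) -> int:
    """Stable 31-bit seed from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def release_points(nest, distance: float, M: int = 10, seed: int = 0) -> np.ndarray:
    """M release points at a fixed distance, equally spaced in angle
    (360/M degrees apart) with a seeded random phase."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 360.0)
    angles = phase + 360.0 * np.arange(M) / M
    nest = np.asarray(nest, dtype=float)
    return nest + distance * np.stack([unit_vector(a) for a in angles])


@dataclass(frozen=True)
class SweepSpec:
    """A (gain x baseline) grid evaluated by the M-release protocol."""

    gain_values: tuple = (0.0, 10.0, 50.0, 250.0, 1250.0, math.inf)
    baseline_values: tuple = (0.0, 36.0, 72.0, 108.0, 144.0, 180.0)
    release_distance: float = 4.0
    M: int = 10
    steps: int = 320
    success_radius: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if any(g < 0 for g in self.gain_values):
            raise ValueError("gains must be >= 0")
        if any(not 0.0 <= b <= 180.0 for b in self.baseline_values):
            raise ValueError("baselines must be in [0, 180]")


@dataclass
class SweepResult:
    """Median arrival distances over the (gain, baseline) grid."""

    spec: SweepSpec
    memory_mode: str
    median_arrival: np.ndarray  # (n_gain, n_baseline)
    runs: list[dict] = field(default_factory=list)

    def success_fraction(self, radius: float | None = None) -> float:
        """Fraction of grid cells whose median arrival is within radius."""
        r = self.spec.success_radius if radius is None else radius
        return float(np.mean(self.median_arrival <= r))

    def best_cell(self) -> dict:
        i, j = np.unravel_index(np.argmin(self.median_arrival),
                                self.median_arrival.shape)
        return {
            "gain": self.spec.gain_values[i],
            "baseline": self.spec.baseline_values[j],
            "median_arrival": float(self.median_arrival[i, j]),
        }

    def save(self, path) -> None:
        out = {
            "memory_mode": self.memory_mode,
            "gain_values": [str(g) if math.isinf(g) else g
                            for g in self.spec.gain_values],
            "baseline_values": list(self.spec.baseline_values),
            "release_distance": self.spec.release_distance,
            "M": self.spec.M,
            "steps": self.spec.steps,
            "seed": self.spec.seed,
            "median_arrival": self.median_arrival.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


def run_sweep(
    world: WorldModel,
    banks: tuple[MemoryBank, MemoryBank],
    ctx: FamiliarityContext,
    spec: SweepSpec = SweepSpec(),
    memory_mode: str = "opponent",
    geometry: ViewGeometry = ViewGeometry(),
    base_params: AgentParams | None = None,
) -> SweepResult:
    """Evaluate every (gain, baseline) cell by the median arrival
    distance of M seeded releases; deterministic given ``spec.seed``."""
    if base_params is None:
        base_params = AgentParams()
    releases = release_points(world.nest, spec.release_distance, spec.M,
                              seed=spec.seed)
    n_g, n_b = len(spec.gain_values), len(spec.baseline_values)
    medians = np.full((n_g, n_b), np.nan)
    runs: list[dict] = []
    for gi, gain in enumerate(spec.gain_values):
        for bi, baseline in enumerate(spec.baseline_values):
            dists = []
            for ri, release in enumerate(releases):
                params = replace(
                    base_params, gain=gain, baseline=baseline,
                    max_steps=spec.steps, memory_mode=memory_mode,
                    seed=_derive_seed(spec.seed, gi, bi, ri),
                )
                path = run_agent(world, banks, ctx, params, release,
                                 geometry=geometry)
                dists.append(path.arrival_distance)
                runs.append({
                    "gain": gain, "baseline": baseline, "release_index": ri,
                    "arrival_distance": path.arrival_distance,
                    "status": path.status,
                })
            medians[gi, bi] = float(np.median(dists))
    return SweepResult(spec=spec, memory_mode=memory_mode,
                       median_arrival=medians, runs=runs)


@dataclass(frozen=True)
class ExperimentConfig:
    """Base configuration of the robustness-condition protocol.

    Defaults follow the full protocol: 3 nest placements (independent
    worlds) x 100 releases at 5 m around each nest, a 30 m travel budget
    per run, opponent memories with the standard learning walk and
    route.  ``n_nests``/``n_releases`` scale the protocol down for
    smoke runs without changing the code path.
    """

    world_archetype: str = "open_distant"
    world_seed: int = 0
    n_nests: int = 3
    n_releases: int = 100
    release_distance: float = 5.0
    travel_budget_m: float = 30.0
    gain: float = 1250.0
    baseline: float = 90.0
    step_length: float = 0.2
    az_resolution: float = 5.0
    lw_span: float = 2.0
    lw_n_views: int = 25
    lw_noise_halfwidth: float = 0.0
    lw_decoupled: bool = False
    seed: int = 0


@dataclass(frozen=True)
class ConditionSpec:
    """One named robustness manipulation; overrides only its own knobs."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValueError(
                f"unknown condition {self.name!r}; known: {CONDITION_NAMES}")

    def apply(self, cfg: ExperimentConfig) -> ExperimentConfig:
        name = self.name
        if name in ("baseline_default", "unfamiliar_release", "decoupled",
                    "noisy_learning_90", "half_memories_10",
                    "coarse_resolution_10deg", "small_learning_walk_10cm",
                    "cluttered_world"):
            overrides = {
                "baseline_default": {},
                "unfamiliar_release": {},
                "decoupled": {"lw_decoupled": True},
                "noisy_learning_90": {"lw_noise_halfwidth": 90.0},
                "half_memories_10": {"lw_n_views": 10},
                "coarse_resolution_10deg": {"az_resolution": 10.0},
                # slower walk near a tiny learning walk: 4x shorter steps,
                # 4x as many (the travel budget fixes total distance)
                "small_learning_walk_10cm": {"lw_span": 0.1, "step_length": 0.05},
                # clutter changes views fast with displacement: halve steps
                "cluttered_world": {"world_archetype": "cluttered_local",
                                    "step_length": 0.1},
            }[name]
            return replace(cfg, **overrides)
        raise AssertionError(name)


@dataclass
class ConditionResult:
    """Arrival-distance distribution of one robustness condition."""

    name: str
    arrival_distances: np.ndarray
    n_runs: int
    quantiles: dict

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "name": self.name, "n_runs": self.n_runs,
                "quantiles": self.quantiles,
                "arrival_distances": self.arrival_distances.tolist(),
            }, fh, indent=1)


def run_condition(
    condition: ConditionSpec | str,
    base_config: ExperimentConfig = ExperimentConfig(),
) -> ConditionResult:
    """Run the boxplot protocol for one condition.

    For each of ``n_nests`` independent nest placements (worlds),
    ``n_releases`` agents are released at ``release_distance`` around the
    nest and walk until the travel budget is spent; the per-run arrival
    distances are pooled.  ``unfamiliar_release`` releases the agents
    around a fictive nest in an unvisited region instead.
    """
    if isinstance(condition, str):
        condition = ConditionSpec(condition)
    cfg = condition.apply(base_config)
    steps = int(round(cfg.travel_budget_m / cfg.step_length))
    geometry = ViewGeometry(az_resolution=cfg.az_resolution)
    arrivals = []
    for nest_i in range(cfg.n_nests):
        world = generate_world(_derive_seed(cfg.world_seed, nest_i),
                               archetype=cfg.world_archetype)
        lw = LearningWalkSpec(
            span_radius=cfg.lw_span, n_views=cfg.lw_n_views,
            orientation_noise_halfwidth=cfg.lw_noise_halfwidth,
            decoupled=cfg.lw_decoupled, seed=_derive_seed(cfg.seed, nest_i, 1),
        )
        banks = build_memory_banks(world, lw, RouteSpec(), geometry)
        ctx = FamiliarityContext(seed=_derive_seed(cfg.seed, nest_i, 2))
        ctx = calibrate_average_world_familiarity(world, ctx, geometry)
        if condition.name == "unfamiliar_release":
            # fictive nest deep in unvisited territory; arrival measured
            # against it, where both banks are uninformative
            goal = world.nest + 0.6 * world.bounds * np.array([1.0, 1.0])
        else:
            goal = world.nest
        releases = release_points(goal, cfg.release_distance, cfg.n_releases,
                                  seed=_derive_seed(cfg.seed, nest_i, 3))
        for ri, release in enumerate(releases):
            params = AgentParams(
                baseline=cfg.baseline, gain=cfg.gain,
                step_length=cfg.step_length, max_steps=steps,
                memory_mode="opponent",
                seed=_derive_seed(cfg.seed, nest_i, 4, ri),
            )
            path = run_agent(world, banks, ctx, params, release,
                             geometry=geometry)
            arrivals.append(
                float(np.hypot(*(path.final_position - goal))))
    arrivals = np.asarray(arrivals)
    qs = {q: float(np.quantile(arrivals, q)) for q in (0.25, 0.5, 0.75)}
    return ConditionResult(
        name=condition.name, arrival_distances=arrivals,
        n_runs=len(arrivals), quantiles=qs,
    )


def homing_success(path: Path, nest, radius: float = 1.0) -> bool:
    """True iff the run ended within ``radius`` of the nest (inclusive)."""
    d = float(np.hypot(*(path.final_position - np.asarray(nest, dtype=float))))
    return d <= radius
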