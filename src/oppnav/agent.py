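"""The closed-loop oscillatory walker.

The agent is a point (x, y) with a heading theta.  A continuously
running oscillator alternates the turn direction left/right every step;
only the turn *amplitude* is modulated by the current visual drive:

    turn_amplitude = clip(baseline - gain * overall_drive, 0, 180)
    theta(t+1)     = theta(t) + turn_amplitude * sign(t) + noise

followed by one fixed-length step forward along the new heading.
Familiar (positive-drive) views straighten the path; unfamiliar
(negative-drive) views sharpen the turns, up to a full U-turn.  An
infinite gain degenerates to the binary rule 0/180 deg with the
baseline kept only at exactly zero drive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import unit_vector, wrap360
from .familiarity import (
    FamiliarityContext,
    attractive_only_drive,
    bank_familiarity,
    opponent_drive,
)
from .memory import MemoryBank
from .world import ViewGeometry, WorldModel, render_panorama


@dataclass(frozen=True)
class AgentParams:
    """Steering-law and run parameters.

    ``baseline`` (deg) is the turn amplitude at zero drive; ``gain``
    (deg per familiarity unit, may be ``math.inf``) converts drive into
    turn modulation.  ``noise_model`` is ``"gaussian"`` (std
    ``noise_deg``), ``"uniform"`` (halfwidth ``noise_deg``) or
    ``"none"``; the noise perturbs the heading after the clipped turn.
    One step is 0.2 m by default.
    """

    baseline: float = 90.0
    gain: float = 1250.0
    step_length: float = 0.2
    noise_model: str = "gaussian"
    noise_deg: float = 10.0
    max_steps: int = 120
    memory_mode: str = "opponent"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 180.0:
            raise ValueError("baseline must be in [0, 180]")
        if self.gain < 0:
            raise ValueError("gain must be >= 0 (math.inf allowed)")
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")
        if self.noise_model not in ("gaussian", "uniform", "none"):
            raise ValueError("noise_model must be gaussian|uniform|none")
        if self.memory_mode not in ("opponent", "attractive_only"):
            raise ValueError("memory_mode must be opponent|attractive_only")


@dataclass
class AgentState:
    """Instantaneous walker state."""

    position: np.ndarray
    theta: float
    t: int = 0
    oscillator_sign: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.theta = float(wrap360(self.theta))
        if self.oscillator_sign not in (1, -1):
            raise ValueError("oscillator_sign must be +1 or -1")


@dataclass
class Path:
    """A recorded trajectory plus its run metadata.

    ``records`` holds one row per executed step: the pre-step position
    and post-turn heading together with the step's familiarity readouts.
    ``positions`` additionally includes the final position, so
    consecutive rows are exactly one step length apart.
    """

    release: np.ndarray
    nest: np.ndarray
    params: AgentParams
    records: list[dict] = field(default_factory=list)
    positions: np.ndarray | None = None
    status: str = "completed"

    @property
    def n_steps(self) -> int:
        return len(self.records)

    @property
    def final_position(self) -> np.ndarray:
        if self.positions is None or len(self.positions) == 0:
            return np.asarray(self.release, dtype=float)
        return self.positions[-1]

    @property
    def arrival_distance(self) -> float:
        """Distance from the nest at the end (or truncation) of the run."""
        return float(np.hypot(*(self.final_position - np.asarray(self.nest))))

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["t", "x", "y", "theta", "turn_amplitude", "oscillator_sign",
                "attractive_familiarity", "repulsive_familiarity", "overall_drive"]
        return pd.DataFrame(self.records, columns=cols)

    def save(self, csv_path, sidecar_path=None) -> None:
        """Write the step records as CSV plus a JSON sidecar of metadata."""
        self.to_dataframe().to_csv(csv_path, index=False)
        if sidecar_path is not None:
            meta = {
                "release": np.asarray(self.release).tolist(),
                "nest": np.asarray(self.nest).tolist(),
                "status": self.status,
                "arrival_distance": self.arrival_distance,
                "final_position": self.final_position.tolist(),
                "params": {
                    k: (str(v) if v in (math.inf,) else v)
                    for k, v in vars(self.params).items()
                },
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def turn_amplitude(drive: float, params: AgentParams) -> float:
    """Turn amplitude (deg) from the overall drive, clipped to [0, 180].

    Infinite gain applies the sign rule: 0 deg for positive drive,
    180 deg for negative, falling back to the baseline at exactly zero.
    """
    if math.isinf(params.gain):
        if drive > 0:
            return 0.0
        if drive < 0:
            return 180.0
        return params.baseline
    return float(np.clip(params.baseline - params.gain * drive, 0.0, 180.0))


def compute_drive(view, attractive: MemoryBank, repulsive: MemoryBank | None,
                  ctx: FamiliarityContext, memory_mode: str):
    """Familiarity readout(s) for one view under the given memory mode."""
    att = bank_familiarity(view, attractive, ctx)
    if memory_mode == "opponent":
        rep = bank_familiarity(view, repulsive, ctx)
        return opponent_drive(att, rep)
    return attractive_only_drive(att, ctx)


def step_agent(
    state: AgentState,
    world: WorldModel,
    banks: tuple[MemoryBank, MemoryBank],
    ctx: FamiliarityContext,
    params: AgentParams,
    rng: np.random.Generator,
    geometry: ViewGeometry = ViewGeometry(),
) -> tuple[AgentState, dict]:
    """Execute one look-turn-step cycle; returns (new state, step record).

    The noise draw happens every step regardless of the noise model so
    that run trajectories with different noise settings stay seeded
    comparably.
    """
    view = render_panorama(world, state.position, state.theta, geometry)
    drive = compute_drive(view, banks[0], banks[1], ctx, params.memory_mode)
    amp = turn_amplitude(drive.overall_drive, params)

    if params.noise_model == "gaussian":
        noise = rng.normal(0.0, params.noise_deg)
    elif params.noise_model == "uniform":
        noise = rng.uniform(-params.noise_deg, params.noise_deg)
    else:
        rng.normal(0.0, 1.0)
        noise = 0.0

    new_theta = wrap360(state.theta + amp * state.oscillator_sign + noise)
    new_position = state.position + params.step_length * unit_vector(new_theta)

    record = {
        "t": state.t,
        "x": float(state.position[0]),
        "y": float(state.position[1]),
        "theta": float(new_theta),
        "turn_amplitude": amp,
        "oscillator_sign": state.oscillator_sign,
        "attractive_familiarity": drive.attractive_familiarity,
        "repulsive_familiarity": (
            np.nan if drive.repulsive_familiarity is None
            else drive.repulsive_familiarity
        ),
        "overall_drive": drive.overall_drive,
    }
    new_state = AgentState(
        position=new_position,
        theta=float(new_theta),
        t=state.t + 1,
        oscillator_sign=-state.oscillator_sign,
    )
    return new_state, record


def run_agent(
    world: WorldModel,
    banks: tuple[MemoryBank, MemoryBank],
    ctx: FamiliarityContext,
    params: AgentParams,
    release,
    initial_heading: float | None = None,
    geometry: ViewGeometry = ViewGeometry(),
) -> Path:
    """Release the agent and iterate the step rules for ``max_steps``.

    The initial heading is drawn uniformly when not given; the initial
    oscillator sign is randomised per run.  A step that leaves the world
    bounds truncates the run with status ``"out_of_world"``.
    """
    release = np.asarray(release, dtype=float)
    if not world.contains(release):
        raise ValueError(f"release point {release.tolist()} outside world bounds")
    rng = np.random.default_rng(params.seed)
    heading = rng.uniform(0.0, 360.0) if initial_heading is None else float(initial_heading)
    sign = 1 if rng.integers(0, 2) == 0 else -1

    state = AgentState(position=release, theta=heading, oscillator_sign=sign)
    path = Path(release=release.copy(), nest=np.asarray(world.nest, dtype=float),
                params=params)
    positions = [release.copy()]
    for _ in range(params.max_steps):
        state, record = step_agent(state, world, banks, ctx, params, rng, geometry)
        path.records.append(record)
        positions.append(state.position.copy())
        if not world.contains(state.position):
            path.status = "out_of_world"
            break
    path.positions = np.asarray(positions)
    return path
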