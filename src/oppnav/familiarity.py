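"""View mismatch, bank familiarity, and the steering drive signals.

Mismatch between two views is the global root-mean-square pixel
difference, computed strictly at the stored facing directions (no
rotational alignment).  Familiarity against a memory bank is one minus
the normalised lowest mismatch over the bank.  Two drive modes exist:

opponent
    overall drive = attractive familiarity - repulsive familiarity,
    the subtraction of the two valence-tagged memory pathways.
attractive_only
    overall drive = attractive familiarity - average world familiarity,
    i.e. the single pathway centred on a world-typical match level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .memory import MemoryBank
from .world import View, ViewGeometry, WorldModel, render_panorama


class EmptyBankError(ValueError):
    """Familiarity was requested against an empty memory bank."""


class CalibrationRequiredError(RuntimeError):
    """Attractive-only drive needs a calibrated average world familiarity."""


@dataclass(frozen=True)
class FamiliarityContext:
    """Normalisation constants for mapping mismatch into familiarity.

    ``normalization_constant`` maps RMS mismatch into [0, 1].  The
    default 1.0 is the theoretical maximum RMS difference between two
    unit-range luminance grids (full-contrast complement), which keeps
    familiarity comparable across worlds; ``normalization_mode
    = "empirical"`` instead uses the largest mismatch seen among the
    calibration views.  ``average_world_familiarity`` is the mean
    familiarity between views at random poses, required by the
    attractive-only drive.
    """

    normalization_constant: float = 1.0
    average_world_familiarity: float | None = None
    n_calibration_views: int = 32
    normalization_mode: str = "theoretical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalization_constant <= 0:
            raise ValueError("normalization_constant must be > 0")
        if self.average_world_familiarity is not None and not (
            0.0 <= self.average_world_familiarity <= 1.0
        ):
            raise ValueError("average_world_familiarity must be in [0, 1]")
        if self.normalization_mode not in ("theoretical", "empirical"):
            raise ValueError("normalization_mode must be theoretical|empirical")


@dataclass(frozen=True)
class DriveSignal:
    """Per-step familiarity readouts and their integration.

    ``repulsive_familiarity`` and ``opponent_familiarity`` are ``None``
    in attractive-only mode.
    """

    attractive_familiarity: float
    repulsive_familiarity: float | None
    opponent_familiarity: float | None
    overall_drive: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.overall_drive):
            raise ValueError("overall_drive must be finite")


def view_mismatch(a: View, b: View) -> float:
    """Global RMS pixel difference between two same-geometry views."""
    if a.shape != b.shape:
        raise ValueError(f"view dimensions differ: {a.shape} vs {b.shape}")
    d = a.pixels - b.pixels
    return float(np.sqrt(np.mean(d * d)))


def normalized_familiarity(rms, ctx: FamiliarityContext):
    """Map RMS mismatch(es) to familiarity in [0, 1]."""
    return 1.0 - np.clip(np.asarray(rms) / ctx.normalization_constant, 0.0, 1.0)


def bank_familiarity(v: View, bank: MemoryBank, ctx: FamiliarityContext) -> float:
    """Familiarity of a view against a bank: 1 - normalised lowest mismatch."""
    if len(bank) == 0:
        raise EmptyBankError("familiarity requested against an empty bank")
    stack = bank.as_array()
    if v.pixels.shape != stack.shape[1:]:
        raise ValueError(
            f"view dimensions {v.pixels.shape} differ from bank views {stack.shape[1:]}"
        )
    d = stack - v.pixels[None, :, :]
    rms = np.sqrt(np.mean(d * d, axis=(1, 2)))
    return float(normalized_familiarity(rms.min(), ctx))


def opponent_drive(att: float, rep: float) -> DriveSignal:
    """Integrate the two memory pathways by subtraction."""
    opp = att - rep
    return DriveSignal(
        attractive_familiarity=att,
        repulsive_familiarity=rep,
        opponent_familiarity=opp,
        overall_drive=opp,
    )


def attractive_only_drive(att: float, ctx: FamiliarityContext) -> DriveSignal:
    """Single-pathway drive, centred on the average world familiarity."""
    if ctx.average_world_familiarity is None:
        raise CalibrationRequiredError(
            "attractive-only drive requires calibrate_average_world_familiarity"
        )
    return DriveSignal(
        attractive_familiarity=att,
        repulsive_familiarity=None,
        opponent_familiarity=None,
        overall_drive=att - ctx.average_world_familiarity,
    )


def calibrate_average_world_familiarity(
    world: WorldModel,
    ctx: FamiliarityContext = FamiliarityContext(),
    geometry: ViewGeometry = ViewGeometry(),
) -> FamiliarityContext:
    """Estimate the world's typical view-to-view familiarity.

    Renders ``n_calibration_views`` views at uniform-random in-bounds
    positions and headings (seeded), then averages familiarity over all
    unordered pairs.  In empirical normalisation mode the normalisation
    constant is first set to the largest pairwise mismatch observed.
    """
    n = ctx.n_calibration_views
    if n < 2:
        raise ValueError("n_calibration_views must be >= 2")
    rng = np.random.default_rng(ctx.seed)
    positions = rng.uniform(-world.bounds, world.bounds, size=(n, 2))
    headings = rng.uniform(0.0, 360.0, size=n)
    views = [render_panorama(world, p, h, geometry) for p, h in zip(positions, headings)]
    rms = np.array([
        view_mismatch(views[i], views[j]) for i, j in combinations(range(n), 2)
    ])
    if ctx.normalization_mode == "empirical":
        ctx = replace(ctx, normalization_constant=float(max(rms.max(), 1e-12)))
    avg = float(np.mean(normalized_familiarity(rms, ctx)))
    return replace(ctx, average_world_familiarity=avg)
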