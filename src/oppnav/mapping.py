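"""Exhaustive familiarity-landscape sampling and its statistics.

A :class:`FamiliarityMap` holds, for every position of a square lattice
centred on the nest and every heading of a uniform angular grid, the
attractive and repulsive bank familiarities and their opponent
difference.  Derived statistics: per-position best direction and
directional specificity (max - median over headings), single-heading
maps and transects, and rank correlations of map values against angular
error and nest distance.

Rendering exploits rotation equivariance: when the heading step is a
multiple of the azimuth resolution, each lattice position is rendered
once and all headings are obtained by circular column shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .angles import angular_distance, bearing, wrap360
from .familiarity import FamiliarityContext, normalized_familiarity
from .memory import MemoryBank
from .world import ViewGeometry, WorldModel, render_panorama


@dataclass(frozen=True)
class GridSpec:
    """Square sampling lattice centred on the nest.

    Defaults reproduce the exhaustive protocol: a 30 x 30 m region
    sampled every 0.5 m (3600 positions) with a 5-degree heading grid
    (72 headings).
    """

    extent: float = 30.0
    spacing: float = 0.5
    centre: tuple[float, float] = (0.0, 0.0)
    headings_step: float = 5.0

    def __post_init__(self) -> None:
        n = self.extent / self.spacing
        if abs(n - round(n)) > 1e-9:
            raise ValueError("extent must be an integral multiple of spacing")
        h = 360.0 / self.headings_step
        if abs(h - round(h)) > 1e-9:
            raise ValueError("headings_step must divide 360")

    @property
    def n_side(self) -> int:
        return round(self.extent / self.spacing)

    @property
    def n_headings(self) -> int:
        return round(360.0 / self.headings_step)

    @property
    def headings(self) -> np.ndarray:
        return np.arange(self.n_headings) * self.headings_step

    def positions(self) -> np.ndarray:
        """Lattice positions, shape (n_side**2, 2), row-major in (x, y)."""
        n = self.n_side
        offsets = (np.arange(n) - (n - 1) / 2.0) * self.spacing
        cx, cy = self.centre
        xs, ys = np.meshgrid(cx + offsets, cy + offsets, indexing="ij")
        return np.column_stack([xs.ravel(), ys.ravel()])


@dataclass
class FamiliarityMap:
    """Sampled familiarity landscape.

    ``attractive``/``repulsive``/``opponent`` have shape
    (n_positions, n_headings); ``valid`` flags in-bounds lattice
    positions (out-of-bounds rows are NaN).
    """

    grid: GridSpec
    nest: np.ndarray
    positions: np.ndarray
    attractive: np.ndarray
    repulsive: np.ndarray
    opponent: np.ndarray
    valid: np.ndarray

    def heading_index(self, heading: float) -> int:
        idx = np.where(np.isclose(self.grid.headings, wrap360(heading)))[0]
        if idx.size == 0:
            raise ValueError(f"heading {heading} not in the sampled heading set")
        return int(idx[0])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (x, y, heading_deg, attractive, repulsive, opponent)."""
        n_pos, n_head = self.attractive.shape
        pos = np.repeat(self.positions, n_head, axis=0)
        heads = np.tile(self.grid.headings, n_pos)
        return pd.DataFrame({
            "x": pos[:, 0], "y": pos[:, 1], "heading_deg": heads,
            "attractive": self.attractive.ravel(),
            "repulsive": self.repulsive.ravel(),
            "opponent": self.opponent.ravel(),
        })

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sample_familiarity_map(
    world: WorldModel,
    banks: tuple[MemoryBank, MemoryBank],
    ctx: FamiliarityContext,
    grid: GridSpec = GridSpec(),
    geometry: ViewGeometry = ViewGeometry(),
) -> FamiliarityMap:
    """Read the familiarity in every direction at every lattice position.

    Out-of-bounds lattice positions are skipped and masked.  When the
    heading step is a multiple of the azimuth resolution a single render
    per position serves all headings via circular shifts.
    """
    att_bank, rep_bank = banks
    att_stack = att_bank.as_array()
    rep_stack = rep_bank.as_array()
    positions = grid.positions()
    n_pos, n_head = positions.shape[0], grid.n_headings

    att = np.full((n_pos, n_head), np.nan)
    rep = np.full((n_pos, n_head), np.nan)
    valid = np.zeros(n_pos, dtype=bool)

    ratio = grid.headings_step / geometry.az_resolution
    shiftable = abs(ratio - round(ratio)) < 1e-9
    shifts = (np.round(grid.headings / geometry.az_resolution).astype(int)
              if shiftable else None)

    for i, p in enumerate(positions):
        if not world.contains(p):
            continue
        valid[i] = True
        if shiftable:
            base = render_panorama(world, p, 0.0, geometry).pixels
            views = np.stack([np.roll(base, s, axis=1) for s in shifts])
        else:
            views = np.stack([
                render_panorama(world, p, h, geometry).pixels
                for h in grid.headings
            ])
        d = views[:, None, :, :] - att_stack[None, :, :, :]
        att[i] = normalized_familiarity(
            np.sqrt(np.mean(d * d, axis=(2, 3))).min(axis=1), ctx)
        d = views[:, None, :, :] - rep_stack[None, :, :, :]
        rep[i] = normalized_familiarity(
            np.sqrt(np.mean(d * d, axis=(2, 3))).min(axis=1), ctx)

    return FamiliarityMap(
        grid=grid, nest=np.asarray(world.nest, dtype=float), positions=positions,
        attractive=att, repulsive=rep, opponent=att - rep, valid=valid,
    )


def best_direction_field(fmap: FamiliarityMap, mode: str = "attractive"):
    """Per-position best heading and directional specificity.

    Specificity is max minus median familiarity over headings, clipped
    to [0, 0.5] for reporting.  Ties in the argmax resolve to the lowest
    heading.  Returns (best_heading_deg, specificity), NaN off-lattice.
    """
    values = _mode_values(fmap, mode)
    n_pos = values.shape[0]
    best_heading = np.full(n_pos, np.nan)
    specificity = np.full(n_pos, np.nan)
    v = values[fmap.valid]
    if v.size:
        best_heading[fmap.valid] = fmap.grid.headings[np.argmax(v, axis=1)]
        specificity[fmap.valid] = np.clip(
            v.max(axis=1) - np.median(v, axis=1), 0.0, 0.5)
    return best_heading, specificity


def single_heading_map(fmap: FamiliarityMap, heading: float, mode: str) -> np.ndarray:
    """Per-position map value at one fixed heading (NaN off-lattice)."""
    return _mode_values(fmap, mode)[:, fmap.heading_index(heading)]


def transect(fmap: FamiliarityMap, heading: float, mode: str,
             axis: str = "x") -> pd.DataFrame:
    """Values along the lattice line through the nest, at one heading.

    ``axis="x"`` walks west-east through the row of lattice positions
    nearest the nest (and vice versa for ``"y"``).
    """
    values = single_heading_map(fmap, heading, mode)
    n = fmap.grid.n_side
    grid_vals = values.reshape(n, n)  # [x index, y index]
    xs = fmap.positions[:, 0].reshape(n, n)
    ys = fmap.positions[:, 1].reshape(n, n)
    if axis == "x":
        j = int(np.argmin(np.abs(ys[0, :] - fmap.nest[1])))
        return pd.DataFrame({"coord": xs[:, j], "value": grid_vals[:, j]})
    if axis == "y":
        i = int(np.argmin(np.abs(xs[:, 0] - fmap.nest[0])))
        return pd.DataFrame({"coord": ys[i, :], "value": grid_vals[i, :]})
    raise ValueError("axis must be 'x' or 'y'")


def angular_error_stats(fmap: FamiliarityMap, heading: float) -> dict:
    """Rank correlations of single-heading map values with directional
    error and with nest distance, for both memory read-out modes.

    The directional error of a position is the angular distance between
    the fixed viewing heading and the bearing from that position to the
    nest.  Spearman correlations; a constant input yields 0 with
    ``degenerate=True``.
    """
    nest_bearings = np.array([bearing(p, fmap.nest) for p in fmap.positions])
    ang_err = angular_distance(heading, nest_bearings)
    dist = np.hypot(*(fmap.positions - fmap.nest).T)

    out = {"heading_deg": float(wrap360(heading))}
    for mode in ("attractive", "opponent"):
        vals = single_heading_map(fmap, heading, mode)
        ok = fmap.valid & np.isfinite(vals)
        degenerate = ok.sum() < 3 or np.allclose(vals[ok], vals[ok][0])
        if degenerate:
            c_ang = c_dist = 0.0
        else:
            c_ang = float(spearmanr(vals[ok], ang_err[ok]).statistic)
            c_dist = float(spearmanr(vals[ok], dist[ok]).statistic)
            c_ang = 0.0 if np.isnan(c_ang) else c_ang
            c_dist = 0.0 if np.isnan(c_dist) else c_dist
        out[mode] = {
            "corr_angular_error": c_ang,
            "corr_nest_distance": c_dist,
            "degenerate": bool(degenerate),
        }
    return out


def _mode_values(fmap: FamiliarityMap, mode: str) -> np.ndarray:
    if mode in ("attractive", "attractive_only"):
        return fmap.attractive
    if mode == "repulsive":
        return fmap.repulsive
    if mode == "opponent":
        return fmap.opponent
    raise ValueError(f"unknown mode {mode!r}")
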