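"""Attractive and repulsive view-memory banks.

The attractive bank holds views memorised while facing the nest: sampled
along a learning-walk spiral around the nest and along a straight homing
route.  The repulsive bank holds views memorised while facing directly
away from the nest at the same (or, optionally, decoupled) spiral
positions.  Banks are constructed, not learned — no plasticity here.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .angles import bearing, unit_vector, wrap360
from .world import View, ViewGeometry, WorldModel, render_panorama


class ConfigurationError(ValueError):
    """A bank specification produced an unusable (empty) memory bank."""


@dataclass
class LearningWalkSpec:
    """Geometry of the learning-walk spiral and its view sampling.

    Defaults: 25 views on a 2 m-radius, 2-turn Archimedean spiral around
    the nest, facing exactly nest-ward (attractive) / anti-nest-ward
    (repulsive).  ``orientation_noise_halfwidth`` adds independent uniform
    noise (degrees) to each stored facing; ``decoupled`` acquires the
    repulsive views on a second, independently-phased spiral.
    """

    span_radius: float = 2.0
    n_views: int = 25
    spiral_turns: float = 2.0
    orientation_noise_halfwidth: float = 0.0
    decoupled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.span_radius <= 0:
            raise ValueError("span_radius must be > 0")
        if not 0.0 <= self.orientation_noise_halfwidth <= 180.0:
            raise ValueError("orientation_noise_halfwidth must be in [0, 180]")


@dataclass
class RouteSpec:
    """A straight foraging route leaving the nest.

    Homing (nest-facing) views are stored every ``view_spacing`` metres
    along it and join the attractive bank; outbound-facing copies join
    the repulsive bank only when ``include_outbound_repulsive`` is set.
    """

    length: float = 10.0
    start_bearing: float = 0.0
    view_spacing: float = 0.5
    include_outbound_repulsive: bool = False

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if self.view_spacing <= 0:
            raise ValueError("view_spacing must be > 0")


@dataclass
class MemoryBank:
    """A valence-tagged collection of memorised views."""

    valence: str
    views: list[View]
    provenance: list[dict] = field(default_factory=list)
    _stack: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.valence not in ("attractive", "repulsive"):
            raise ValueError(f"valence must be attractive|repulsive, got {self.valence!r}")
        shapes = {v.shape for v in self.views}
        if len(shapes) > 1:
            raise ValueError("all views in a bank must share the same geometry")

    def __len__(self) -> int:
        return len(self.views)

    def as_array(self) -> np.ndarray:
        """All view pixel grids stacked as (n_views, rows, cols), cached."""
        if self._stack is None or self._stack.shape[0] != len(self.views):
            self._stack = np.stack([v.pixels for v in self.views])
        return self._stack

    def save(self, directory) -> None:
        """Write one CSV per view plus a JSON manifest."""
        os.makedirs(directory, exist_ok=True)
        manifest = {"valence": self.valence, "views": []}
        for i, (v, prov) in enumerate(zip(self.views, self.provenance)):
            fname = f"view_{i:04d}.csv"
            v.to_csv(os.path.join(directory, fname))
            manifest["views"].append({
                "file": fname,
                "position": v.position.tolist(),
                "heading": v.heading,
                "az_resolution": v.az_resolution,
                "elev_span": list(v.elev_span),
                "provenance": prov,
            })
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "MemoryBank":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        views, prov = [], []
        for rec in manifest["views"]:
            pixels = np.loadtxt(os.path.join(directory, rec["file"]), delimiter=",",
                                ndmin=2)
            views.append(View(
                pixels=pixels,
                position=np.asarray(rec["position"]),
                heading=rec["heading"],
                az_resolution=rec["az_resolution"],
                elev_span=tuple(rec["elev_span"]),
            ))
            prov.append(rec.get("provenance", {}))
        return cls(valence=manifest["valence"], views=views, provenance=prov)


def spiral_positions(nest, spec: LearningWalkSpec, phase_deg: float = 0.0) -> np.ndarray:
    """Sample points of the learning-walk spiral, shape (n_views, 2).

    Archimedean spiral centred on the nest: radius grows uniformly from
    ``span_radius / n_views`` out to ``span_radius`` while the angle
    advances uniformly over ``spiral_turns`` revolutions (optionally
    phase-shifted).  Deterministic.
    """
    nest = np.asarray(nest, dtype=float)
    n = spec.n_views
    radii = spec.span_radius * np.arange(1, n + 1) / n
    angles = phase_deg + np.arange(n) * (360.0 * spec.spiral_turns / n)
    rad = np.radians(angles)
    return nest + np.column_stack([radii * np.cos(rad), radii * np.sin(rad)])


def route_positions(nest, route: RouteSpec) -> np.ndarray:
    """View sample points along the straight route, nest excluded."""
    n = int(round(route.length / route.view_spacing))
    if n == 0:
        return np.empty((0, 2))
    dists = route.view_spacing * np.arange(1, n + 1)
    u = unit_vector(route.start_bearing)
    return np.asarray(nest, dtype=float) + dists[:, None] * u[None, :]


def build_memory_banks(
    world: WorldModel,
    lw: LearningWalkSpec = LearningWalkSpec(),
    route: RouteSpec = RouteSpec(),
    geometry: ViewGeometry = ViewGeometry(),
) -> tuple[MemoryBank, MemoryBank]:
    """Render the attractive and repulsive memory banks.

    Attractive: nest-facing spiral views (facing = bearing to nest, plus
    uniform orientation noise) followed by nest-facing route views.
    Repulsive: anti-nest-facing spiral views (180 deg from the pre-noise
    attractive facing, with independent noise), at the same spiral
    positions or on an independently-phased spiral when decoupled.
    """
    rng = np.random.default_rng(lw.seed)
    hw = lw.orientation_noise_halfwidth

    att_pos = spiral_positions(world.nest, lw)
    att_noise = rng.uniform(-hw, hw, lw.n_views)
    if lw.decoupled:
        # independently generated spiral: random phase offset keeps the
        # two position sets disjoint
        phase = rng.uniform(1.0, 359.0)
        rep_pos = spiral_positions(world.nest, lw, phase_deg=phase)
    else:
        rep_pos = att_pos
    rep_noise = rng.uniform(-hw, hw, lw.n_views)

    att_views, att_prov = [], []
    for p, dn in zip(att_pos, att_noise):
        facing = bearing(p, world.nest)
        att_views.append(render_panorama(world, p, facing + dn, geometry))
        att_prov.append({"kind": "learning_walk", "position": p.tolist(),
                         "intended_facing": facing, "applied_noise": float(dn)})
    rep_views, rep_prov = [], []
    for p, dn in zip(rep_pos, rep_noise):
        facing = wrap360(bearing(p, world.nest) + 180.0)
        rep_views.append(render_panorama(world, p, facing + dn, geometry))
        rep_prov.append({"kind": "learning_walk", "position": p.tolist(),
                         "intended_facing": float(facing), "applied_noise": float(dn)})

    for p in route_positions(world.nest, route):
        facing = bearing(p, world.nest)
        att_views.append(render_panorama(world, p, facing, geometry))
        att_prov.append({"kind": "route", "position": p.tolist(),
                         "intended_facing": facing, "applied_noise": 0.0})
        if route.include_outbound_repulsive:
            out = wrap360(facing + 180.0)
            rep_views.append(render_panorama(world, p, out, geometry))
            rep_prov.append({"kind": "route", "position": p.tolist(),
                             "intended_facing": float(out), "applied_noise": 0.0})

    if not att_views or not rep_views:
        raise ConfigurationError("memory bank specification produced an empty bank")
    return (
        MemoryBank("attractive", att_views, att_prov),
        MemoryBank("repulsive", rep_views, rep_prov),
    )
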