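"""Procedural worlds and single-channel panoramic rendering.

A :class:`WorldModel` is a flat plane holding a nest, a set of opaque
vertical cylinders (trees, tussocks, stones) and a 360-degree distant
skyline profile.  Panoramas are rendered with a column-wise occlusion
painter: for each azimuth column the nearest object subtending that
azimuth (else the distant skyline) sets the height and luminance of the
terrestrial silhouette, and everything above it is sky.  This reproduces
the skyline/contrast structure that dominates low-resolution panoramic
vision while staying exactly testable.

Two world archetypes are provided:

``open_distant``
    A large open scene: sparse tall objects plus a non-flat distant
    panorama (forest edge / horizon profile), the kind of habitat where
    distal cues are available from tens of metres.
``cluttered_local``
    A small, densely cluttered scene with a flat horizon: guidance
    information comes entirely from nearby objects.

Units: metres for positions, degrees for angles, luminance in [0, 1]
with the sky fixed brightest (uniform-sky contrast against terrain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .angles import wrap180, wrap360

#: Agent eye height above ground (metres); enters only through the angular
#: elevation of object tops.
EYE_HEIGHT_M = 0.02

#: Skyline profiles are tabulated once per degree of azimuth.
SKYLINE_N_SAMPLES = 360


class OutOfWorldError(ValueError):
    """A position outside the world's square bounds was used."""


@dataclass(frozen=True)
class SceneObject:
    """An opaque vertical cylinder standing on the ground plane."""

    x: float
    y: float
    radius: float
    height: float
    luminance: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.height <= 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if not 0.0 <= self.luminance <= 1.0:
            raise ValueError(f"luminance must be in [0, 1], got {self.luminance}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class ViewGeometry:
    """Sampling geometry of the panoramic eye.

    Defaults follow typical ant compound-eye resolution: 5 deg/pixel in
    azimuth (72 columns) and the same vertically over the above-horizon
    span 0-60 deg (12 rows).  Below-horizon content is never rendered.
    """

    az_resolution: float = 5.0
    elev_span: tuple[float, float] = (0.0, 60.0)
    elev_resolution: float | None = None

    def __post_init__(self) -> None:
        n_cols = 360.0 / self.az_resolution
        if abs(n_cols - round(n_cols)) > 1e-9:
            raise ValueError(
                f"az_resolution must divide 360, got {self.az_resolution}"
            )
        lo, hi = self.elev_span
        if lo < 0:
            raise ValueError("elev_span minimum must be >= 0 (below-horizon cropped)")
        if hi <= lo:
            raise ValueError("elev_span must be increasing")
        res = self.elev_resolution if self.elev_resolution is not None else self.az_resolution
        n_rows = (hi - lo) / res
        if abs(n_rows - round(n_rows)) > 1e-9:
            raise ValueError("elevation resolution must divide the elevation span")

    @property
    def n_cols(self) -> int:
        return round(360.0 / self.az_resolution)

    @property
    def elev_res(self) -> float:
        return self.elev_resolution if self.elev_resolution is not None else self.az_resolution

    @property
    def n_rows(self) -> int:
        lo, hi = self.elev_span
        return round((hi - lo) / self.elev_res)


@dataclass
class View:
    """A rendered single-channel panorama tied to a pose.

    ``pixels[0]`` is the highest-elevation row; columns start at the
    heading direction and advance clockwise in the visual field.
    """

    pixels: np.ndarray
    position: np.ndarray
    heading: float
    az_resolution: float
    elev_span: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        n_cols = self.pixels.shape[1]
        if abs(n_cols * self.az_resolution - 360.0) > 1e-9:
            raise ValueError("cols x az_resolution must equal 360")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.elev_span[0] < 0:
            raise ValueError("elev_span minimum must be >= 0")
        self.heading = float(wrap360(self.heading))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_csv(self, path) -> None:
        """Write the pixel grid as plain CSV (top row = highest elevation)."""
        np.savetxt(path, self.pixels, delimiter=",", fmt="%.6f")

    def to_pgm(self, path, levels: int = 255) -> None:
        """Write an ASCII PGM greyscale image for quick inspection."""
        grid = np.round(self.pixels * levels).astype(int)
        rows, cols = grid.shape
        with open(path, "w") as fh:
            fh.write(f"P2\n{cols} {rows}\n{levels}\n")
            for row in grid:
                fh.write(" ".join(str(v) for v in row) + "\n")


@dataclass
class WorldModel:
    """A navigable scene: nest, clutter objects, distant skyline.

    ``bounds`` is the half-width of the square navigable region centred
    on the origin.  ``skyline_elevation_deg`` / ``skyline_luminance`` are
    per-degree profiles (360 samples, azimuth 0..359 deg CCW from +x).
    """

    nest: np.ndarray
    objects: list[SceneObject]
    skyline_elevation_deg: np.ndarray
    skyline_luminance: np.ndarray
    bounds: float
    ground_luminance: float = 0.4
    sky_luminance: float = 1.0
    seed: int | None = None
    archetype: str | None = None
    _arrays: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nest = np.asarray(self.nest, dtype=float)
        self.skyline_elevation_deg = np.asarray(self.skyline_elevation_deg, dtype=float)
        self.skyline_luminance = np.asarray(self.skyline_luminance, dtype=float)
        if self.bounds <= 0:
            raise ValueError(f"bounds must be > 0, got {self.bounds}")
        if self.skyline_elevation_deg.shape != (SKYLINE_N_SAMPLES,):
            raise ValueError("skyline profile must cover 360 deg (360 samples)")
        if self.skyline_luminance.shape != (SKYLINE_N_SAMPLES,):
            raise ValueError("skyline luminance must cover 360 deg (360 samples)")
        if self.sky_luminance == self.ground_luminance:
            raise ValueError("sky/ground contrast must be nonzero")

    def contains(self, position) -> bool:
        x, y = np.asarray(position, dtype=float)
        return bool(abs(x) <= self.bounds and abs(y) <= self.bounds)

    def object_arrays(self) -> dict:
        """Object fields as flat arrays, cached for the render hot loop."""
        if not self._arrays:
            if self.objects:
                self._arrays = {
                    "xy": np.array([[o.x, o.y] for o in self.objects]),
                    "radius": np.array([o.radius for o in self.objects]),
                    "height": np.array([o.height for o in self.objects]),
                    "luminance": np.array([o.luminance for o in self.objects]),
                }
            else:
                self._arrays = {
                    "xy": np.empty((0, 2)),
                    "radius": np.empty(0),
                    "height": np.empty(0),
                    "luminance": np.empty(0),
                }
        return self._arrays

    # -- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nest": self.nest.tolist(),
            "objects": [
                {"x": o.x, "y": o.y, "radius": o.radius, "height": o.height,
                 "luminance": o.luminance}
                for o in self.objects
            ],
            "skyline_elevation_deg": self.skyline_elevation_deg.tolist(),
            "skyline_luminance": self.skyline_luminance.tolist(),
            "bounds": self.bounds,
            "ground_luminance": self.ground_luminance,
            "sky_luminance": self.sky_luminance,
            "seed": self.seed,
            "archetype": self.archetype,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "WorldModel":
        return cls(
            nest=np.asarray(d["nest"], dtype=float),
            objects=[SceneObject(**o) for o in d["objects"]],
            skyline_elevation_deg=np.asarray(d["skyline_elevation_deg"], dtype=float),
            skyline_luminance=np.asarray(d["skyline_luminance"], dtype=float),
            bounds=float(d["bounds"]),
            ground_luminance=float(d.get("ground_luminance", 0.4)),
            sky_luminance=float(d.get("sky_luminance", 1.0)),
            seed=d.get("seed"),
            archetype=d.get("archetype"),
        )

    @classmethod
    def load(cls, path) -> "WorldModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def skyline_from_profile(points: Sequence[dict]) -> tuple[np.ndarray, np.ndarray]:
    """Build per-degree skyline arrays from a sparse user profile.

    ``points`` is a list of ``{"azimuth_deg", "elevation_deg", "luminance"}``
    records; values are interpolated circularly onto the 1-degree grid.
    """
    if not points:
        raise ValueError("profile must contain at least one point")
    pts = sorted(points, key=lambda p: wrap360(p["azimuth_deg"]))
    az = np.array([wrap360(p["azimuth_deg"]) for p in pts], dtype=float)
    elev = np.array([p["elevation_deg"] for p in pts], dtype=float)
    lum = np.array([p["luminance"] for p in pts], dtype=float)
    grid = np.arange(SKYLINE_N_SAMPLES, dtype=float)
    # circular interpolation: pad one wrapped point on each side
    az_ext = np.concatenate([[az[-1] - 360.0], az, [az[0] + 360.0]])
    elev_ext = np.concatenate([[elev[-1]], elev, [elev[0]]])
    lum_ext = np.concatenate([[lum[-1]], lum, [lum[0]]])
    return np.interp(grid, az_ext, elev_ext), np.interp(grid, az_ext, lum_ext)


def load_skyline_profile(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a custom skyline-profile JSON file (list of azimuth records)."""
    with open(path) as fh:
        return skyline_from_profile(json.load(fh))


def generate_world(
    seed: int,
    archetype: str = "open_distant",
    n_objects: int | None = None,
    bounds: float | None = None,
) -> WorldModel:
    """Procedurally generate a world of the given archetype.

    Deterministic in ``seed``.  ``open_distant`` defaults to a 64 x 64 m
    region (bounds 32) with 20 sparse tall objects and a non-flat distant
    skyline; ``cluttered_local`` to a 20 x 20 m region (bounds 10) with
    200 small objects and a flat horizon.
    """
    if archetype not in ("open_distant", "cluttered_local"):
        raise ValueError(f"unknown archetype: {archetype!r}")
    if bounds is None:
        bounds = 32.0 if archetype == "open_distant" else 10.0
    if bounds <= 0:
        raise ValueError(f"bounds must be > 0, got {bounds}")
    if n_objects is None:
        n_objects = 20 if archetype == "open_distant" else 200
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")

    rng = np.random.default_rng(seed)
    az = np.arange(SKYLINE_N_SAMPLES, dtype=float)

    if archetype == "open_distant":
        # smooth non-flat horizon: a few low-order harmonics, elevations
        # of a distant forest edge / ridge line (a few degrees)
        elev = np.full(SKYLINE_N_SAMPLES, 6.0)
        for k in (1, 2, 3):
            amp = rng.uniform(1.0, 4.0) / k
            phase = rng.uniform(0.0, 360.0)
            elev += amp * np.sin(np.radians(k * az + phase))
        elev = np.clip(elev, 0.0, None)
        sky_lum = 0.25 + 0.1 * np.sin(np.radians(az + rng.uniform(0, 360)))
        # open woodland: a ring of large far trees dominates the visual
        # mass (smooth parallax over tens of metres) plus a few
        # mid-field trees; all clear of the nest / learning-walk area
        # and of the walkable corridor east of the nest where foraging
        # routes run
        n_large = max(n_objects - n_objects // 6, 1) if n_objects else 0
        n_mid = n_objects - n_large
        route_clear = min(12.0, 0.5 * bounds)
        objects = _place_objects(
            rng, n_large, bounds,
            radius_range=(1.5, 3.5), height_range=(15.0, 30.0),
            luminance_range=(0.05, 0.45), nest_clearance=3.0,
            route_clearance=route_clear,
            radial_range=(0.47 * bounds, 0.94 * bounds),
        )
        objects += _place_objects(
            rng, n_mid, bounds,
            radius_range=(0.5, 1.2), height_range=(5.0, 12.0),
            luminance_range=(0.05, 0.45), nest_clearance=3.0,
            route_clearance=route_clear,
            radial_range=(0.25 * bounds, 0.56 * bounds),
        )
    else:
        # flat horizon: no distal panorama at all
        elev = np.zeros(SKYLINE_N_SAMPLES)
        sky_lum = np.full(SKYLINE_N_SAMPLES, 0.3)
        # dense low clutter over the whole arena, clear of the nest
        # itself and of a short route corridor
        objects = _place_objects(
            rng, n_objects, bounds,
            radius_range=(0.05, 0.3), height_range=(0.2, 1.2),
            luminance_range=(0.05, 0.5), nest_clearance=0.5,
            route_clearance=min(10.0, 0.5 * bounds),
            radial_range=(0.5, 0.95 * bounds),
        )
    return WorldModel(
        nest=np.zeros(2),
        objects=objects,
        skyline_elevation_deg=elev,
        skyline_luminance=sky_lum,
        bounds=float(bounds),
        seed=seed,
        archetype=archetype,
    )


def _place_objects(
    rng: np.random.Generator,
    n_objects: int,
    bounds: float,
    radius_range: tuple[float, float],
    height_range: tuple[float, float],
    luminance_range: tuple[float, float],
    nest_clearance: float,
    route_clearance: float,
    radial_range: tuple[float, float] | None = None,
) -> list[SceneObject]:
    """Rejection-sample object positions on an annulus around the nest.

    Objects keep clear of the nest / learning-walk area and of the
    walkable corridor along +x (out to ``route_clearance`` metres) where
    the default foraging route runs — routes follow walkable ground.
    """
    if radial_range is None:
        radial_range = (nest_clearance, 0.9 * bounds)
    objects: list[SceneObject] = []
    attempts = 0
    while len(objects) < n_objects and attempts < 200 * max(n_objects, 1):
        attempts += 1
        r = rng.uniform(*radial_range)
        theta = rng.uniform(0.0, 2 * np.pi)
        x, y = r * np.cos(theta), r * np.sin(theta)
        radius = rng.uniform(*radius_range)
        # distance from the route segment (0,0)-(route_clearance, 0)
        seg_d = abs(y) if 0.0 <= x <= route_clearance else min(
            np.hypot(x, y), np.hypot(x - route_clearance, y))
        if seg_d < radius + 0.8 or np.hypot(x, y) < radius + nest_clearance:
            continue
        objects.append(SceneObject(
            float(x), float(y), float(radius),
            float(rng.uniform(*height_range)),
            float(rng.uniform(*luminance_range)),
        ))
    return objects


def render_panorama(
    world: WorldModel,
    position,
    heading: float,
    geometry: ViewGeometry = ViewGeometry(),
) -> View:
    """Render the panoramic view at a pose by column-wise occlusion.

    For each azimuth column the nearest object subtending that azimuth —
    else the distant skyline — paints the column from the bottom of the
    view up to its top elevation with its luminance; bins above take the
    sky luminance.  Column 0 looks along ``heading``; columns advance
    clockwise in the visual field.
    """
    position = np.asarray(position, dtype=float)
    if not world.contains(position):
        raise OutOfWorldError(f"position {position.tolist()} outside bounds +-{world.bounds}")

    n_cols, n_rows = geometry.n_cols, geometry.n_rows
    elev_lo, elev_hi = geometry.elev_span
    # column azimuths in world coordinates (CCW), clockwise across the view
    col_az = heading - np.arange(n_cols) * geometry.az_resolution
    # row centre elevations, top row first
    row_elev = elev_hi - (np.arange(n_rows) + 0.5) * geometry.elev_res

    arrays = world.object_arrays()
    n_obj = arrays["xy"].shape[0]

    # distant skyline as default occluder per column
    sky_idx = np.floor(wrap360(col_az)).astype(int) % SKYLINE_N_SAMPLES
    top = world.skyline_elevation_deg[sky_idx].copy()
    lum = world.skyline_luminance[sky_idx].copy()

    if n_obj:
        d_xy = arrays["xy"] - position
        dist = np.hypot(d_xy[:, 0], d_xy[:, 1])
        obj_bearing = np.degrees(np.arctan2(d_xy[:, 1], d_xy[:, 0]))
        half_width = np.degrees(np.arctan2(arrays["radius"], dist))
        obj_top = np.degrees(np.arctan2(arrays["height"] - EYE_HEIGHT_M, dist))
        inside = dist <= arrays["radius"]
        if inside.any():
            half_width = np.where(inside, 180.0, half_width)
            obj_top = np.where(inside, 90.0, obj_top)

        diff = wrap180(col_az[:, None] - obj_bearing[None, :])
        covered = np.abs(diff) <= half_width[None, :]
        dist_masked = np.where(covered, dist[None, :], np.inf)
        nearest = np.argmin(dist_masked, axis=1)
        has_obj = np.isfinite(dist_masked[np.arange(n_cols), nearest])
        top = np.where(has_obj, obj_top[nearest], top)
        lum = np.where(has_obj, arrays["luminance"][nearest], lum)

    pixels = np.where(row_elev[:, None] <= top[None, :], lum[None, :],
                      world.sky_luminance)
    return View(
        pixels=pixels,
        position=position,
        heading=heading,
        az_resolution=geometry.az_resolution,
        elev_span=geometry.elev_span,
    )
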