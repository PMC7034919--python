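"""Shared fixtures: the canonical open world, its banks and context.

Session-scoped because bank construction renders 70 panoramas; all
tests treat these objects as read-only.
"""

import numpy as np
import pytest

import oppnav as on


@pytest.fixture(scope="session")
def open_world():
    return on.generate_world(0, "open_distant")


@pytest.fixture(scope="session")
def banks(open_world):
    return on.build_memory_banks(open_world)


@pytest.fixture(scope="session")
def ctx(open_world):
    return on.calibrate_average_world_familiarity(open_world)


@pytest.fixture(scope="session")
def cluttered_world():
    return on.generate_world(2, "cluttered_local")


@pytest.fixture()
def empty_flat_world():
    """No objects, zero skyline: every view is pure sky above 0 deg."""
    return on.WorldModel(
        nest=np.zeros(2),
        objects=[],
        skyline_elevation_deg=np.zeros(360),
        skyline_luminance=np.full(360, 0.3),
        bounds=16.0,
    )


def make_view(pixels, az_resolution=None, heading=0.0):
    """Wrap a raw pixel grid in a View with consistent geometry."""
    pixels = np.asarray(pixels, dtype=float)
    rows, cols = pixels.shape
    az_res = 360.0 / cols if az_resolution is None else az_resolution
    return on.View(
        pixels=pixels, position=np.zeros(2), heading=heading,
        az_resolution=az_res, elev_span=(0.0, rows * 5.0),
    )
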