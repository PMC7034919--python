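"""Angle conventions and helpers.

Headings are degrees counter-clockwise from +x (east), wrapped to [0, 360).
In the visual field, azimuth columns increase clockwise (to the agent's
right), so column ``j`` of a panorama looks along ``heading - j * az_res``.
"""

from __future__ import annotations

import numpy as np


def wrap360(angle_deg):
    """Wrap angle(s) into [0, 360)."""
    return np.mod(angle_deg, 360.0)


def wrap180(angle_deg):
    """Wrap angle(s) into [-180, 180)."""
    return np.mod(np.asarray(angle_deg) + 180.0, 360.0) - 180.0


def angular_distance(a_deg, b_deg):
    """Smallest absolute angular separation between two headings, in [0, 180]."""
    return np.abs(wrap180(np.asarray(a_deg) - np.asarray(b_deg)))


def bearing(from_xy, to_xy):
    """Heading (deg CCW from +x, in [0, 360)) of the vector from -> to."""
    from_xy = np.asarray(from_xy, dtype=float)
    to_xy = np.asarray(to_xy, dtype=float)
    d = to_xy - from_xy
    return float(wrap360(np.degrees(np.arctan2(d[1], d[0]))))


def unit_vector(heading_deg):
    """Unit 2-vector pointing along a heading."""
    rad = np.radians(heading_deg)
    return np.array([np.cos(rad), np.sin(rad)])
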