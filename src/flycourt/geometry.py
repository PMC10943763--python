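"""Shared planar geometry in image coordinates.

All coordinates are 0-based ``(row, col)`` with the origin at the top-left
pixel.  Angles are measured in degrees from the +col axis, counter-clockwise
positive, so the unit vector of angle ``a`` is ``(-sin a, cos a)``.  Under
this convention a fly heading at 90 deg points "up" the image (decreasing
row index).
"""

from __future__ import annotations

import numpy as np


def unit_vector(angle_deg: float) -> np.ndarray:
    """Unit (row, col) vector for an angle in degrees."""
    a = np.deg2rad(angle_deg)
    return np.array([-np.sin(a), np.cos(a)], dtype=float)


def vector_angle(vec) -> float:
    """Angle in degrees of a (row, col) vector, in [0, 360)."""
    r, c = float(vec[0]), float(vec[1])
    return float(np.rad2deg(np.arctan2(-r, c)) % 360.0)


def cross2(u, v) -> float:
    """Scalar cross product of two (row, col) vectors.

    Positive when ``v`` lies counter-clockwise of ``u`` (the fly's left
    side when ``u`` is the heading).
    """
    return float(u[0]) * float(v[1]) - float(u[1]) * float(v[0])


def angle_between(u, v) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(np.dot(np.asarray(u, float), np.asarray(v, float)) / (nu * nv), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(c)))


def rotate_about(point, center, angle_deg: float) -> np.ndarray:
    """Rotate a (row, col) point about a center, counter-clockwise degrees."""
    a = np.deg2rad(angle_deg)
    dr = point[0] - center[0]
    dc = point[1] - center[1]
    # CCW in this convention: col behaves like x, -row like y.
    dc2 = dc * np.cos(a) + dr * np.sin(a)
    dr2 = -dc * np.sin(a) + dr * np.cos(a)
    return np.array([center[0] + dr2, center[1] + dc2], dtype=float)
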