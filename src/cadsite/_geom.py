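"""Small vector-geometry kernel: angles, dihedrals, NeRF placement, axis rotations.

Everything works on float64 numpy arrays of shape (3,) (or (N, 3) where noted)
and degrees, the unit the rest of the package speaks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle_deg",
    "dihedral_deg",
    "nerf",
    "rotation_about_axis",
    "circular_diff_deg",
    "unit",
]


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees in [0, 180]."""
    u = unit(np.asarray(a, float) - np.asarray(b, float))
    w = unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral_deg(a, b, c, d) -> float:
    """Signed torsion a-b-c-d, IUPAC right-handed convention, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so that |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees). Natural-extension reference frame."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(point: np.ndarray, axis: np.ndarray, theta_deg: float):
    """Return f(X) rotating points (N, 3) by theta about the line through
    `point` with direction `axis` (right-hand rule)."""
    point = np.asarray(point, float)
    k = unit(np.asarray(axis, float))
    t = np.radians(theta_deg)
    ct, st = np.cos(t), np.sin(t)

    def apply(x: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(x, float)) - point
        rot = v * ct + np.cross(k, v) * st + np.outer(v @ k, k) * (1.0 - ct)
        out = rot + point
        return out[0] if np.asarray(x).ndim == 1 else out

    return apply


def circular_diff_deg(a: float, b: float) -> float:
    """Absolute angular difference on the circle, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)
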