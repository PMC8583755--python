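"""Low-level vector geometry shared by the chain builder and feature code.

All coordinates are in nanometres, all angles in degrees unless a function
says otherwise.  These are small, well-tested primitives: signed torsions,
internal-coordinate (NeRF) atom placement, Kabsch superposition, and
minimum-image distances for cubic periodic boxes.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle_between",
    "nerf_place",
    "kabsch_rotation",
    "superpose",
    "rmsd_fitted",
    "minimum_image_dists",
]


def dihedral(p0, p1, p2, p3):
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180].

    Accepts single points of shape (3,) or stacked arrays of shape (..., 3);
    the torsion is computed along the last axis.  Degenerate (colinear)
    geometries return NaN rather than raising.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.cross(n1, b1 / b1n)
        x = np.sum(n1 * n2, axis=-1)
        y = -np.sum(m1 * n2, axis=-1)
        ang = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < 1e-12) | (np.linalg.norm(n2, axis=-1) < 1e-12)
    ang = np.where(bad, np.nan, ang)
    # fold -180 -> 180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    if ang.ndim == 0:
        return float(ang)
    return ang


def angle_between(a, b, c):
    """Angle a-b-c in degrees for points of shape (..., 3)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = a - b
    v = c - b
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    out = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def nerf_place(a, b, c, bond: float, angle: float, torsion: float):
    """Place atom d with |d-c| = bond, angle(d,c,b) = angle and
    dihedral(a,b,c,d) = torsion (degrees).  Natural-extension reference
    frame construction; a, b, c must not be colinear.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle)
    chi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("reference atoms are colinear; torsion undefined")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R minimising ||R P^T - Q^T|| for centred
    point sets P, Q of shape (n, 3) (rows are points; apply as P @ R.T).
    """
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` best fits target.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    R = kabsch_rotation(mobile - cm, target - ct)
    t = ct - cm @ R.T
    return R, t


def rmsd_fitted(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD (nm) after optimal rigid superposition, non-mass-weighted."""
    R, t = superpose(mobile, target)
    diff = mobile @ R.T + t - target
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=-1))))


def minimum_image_dists(points_a: np.ndarray, points_b: np.ndarray, box_edge: float):
    """Pairwise minimum-image distances in a cubic box.

    points_a: (n, 3); points_b: (m, 3); returns (n, m).
    """
    a = np.asarray(points_a, float)[:, None, :]
    b = np.asarray(points_b, float)[None, :, :]
    d = a - b
    d -= box_edge * np.round(d / box_edge)
    return np.sqrt(np.sum(d * d, axis=-1))
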