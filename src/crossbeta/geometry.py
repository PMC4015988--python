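"""Small 3D geometry helpers shared by the builder and the observables.

All coordinates are in nm, all angles in degrees unless noted. These are
deliberately plain numpy routines: the systems handled here are tiny
(hundreds of atoms), so clarity beats vectorised cleverness.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "bond_angle",
    "rotation_matrix",
    "unit",
    "fit_plane_normal",
    "angle_between",
]


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Unsigned angle between two vectors, in degrees, in [0, 180]."""
    c = float(np.dot(unit(v1), unit(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    return angle_between(a - b, c - b)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place a new atom D from internal coordinates (NeRF construction).

    D is at distance ``bond`` from c, with angle b-c-D = ``angle`` and
    torsion a-b-c-D = ``torsion`` (degrees).
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about ``axis`` (need not be unit) by ``angle_deg``."""
    ax = unit(np.asarray(axis, dtype=float))
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    x, y, z = ax
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * K + (1.0 - c) * np.outer(ax, ax)


def rigid_rmsd(ref: np.ndarray, mov: np.ndarray) -> float:
    """Minimum RMSD between two conformations after optimal superposition.

    Plain (unweighted) Kabsch alignment; measures internal deformation
    irrespective of rigid-body motion.
    """
    a = ref - ref.mean(axis=0)
    b = mov - mov.mean(axis=0)
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    ssd = (a**2).sum() + (b**2).sum() - 2.0 * (s[0] + s[1] + d * s[2])
    return float(np.sqrt(max(ssd, 0.0) / len(a)))


def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ``points`` (n x 3), via SVD."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]
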