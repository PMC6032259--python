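"""Small 3D geometry helpers shared across the package.

All coordinates are in Ångström, right-handed frames, angles in degrees
at the public surface (radians internally where noted).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "dihedral",
    "bond_angle",
    "place_atom",
    "rotation_about_axis",
    "kabsch_rmsd",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return v / |v|; raises on zero-length input."""
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length vector has no direction")
    return np.asarray(v, dtype=float) / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, w = unit(np.asarray(a) - b), unit(np.asarray(c) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |d-c| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees). Natural extension reference frame."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # local displacement in the frame of the b->c bond
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about *axis*."""
    ax = unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = ax
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(ax, ax)


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD between point sets p and q after optimal superposition."""
    p = np.asarray(p, float) - np.mean(p, axis=0)
    q = np.asarray(q, float) - np.mean(q, axis=0)
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = p @ r.T - q
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
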