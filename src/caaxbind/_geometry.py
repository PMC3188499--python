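"""Internal-coordinate geometry: torsion/angle measurement and NeRF atom placement.

All angles in this module are in degrees at the API surface; torsions follow the
IUPAC sign convention (right-handed, range (-180, 180]).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "bond_length",
    "bond_angle",
    "dihedral",
    "place_atom",
    "rotation_matrix",
]


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-length vector")
    return v / n


def bond_length(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(b - a))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = normalize(a - b)
    v = normalize(c - b)
    cosang = np.clip(np.dot(u, v), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, range (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d bonded to c with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (NeRF construction)."""
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bc = normalize(c - b)
    n = normalize(np.cross(bc, b - a))
    m = np.cross(bc, n)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (axis * angle-in-radians)."""
    theta = np.linalg.norm(rotvec)
    if theta < 1e-12:
        return np.eye(3)
    k = rotvec / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
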