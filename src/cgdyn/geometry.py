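"""Scalar/vector geometry helpers: angles, dihedrals, NeRF atom placement,
Kabsch superposition.  Pure NumPy, no gradient recording; the differentiable
counterparts used inside the force loop live in :mod:`cgdyn.dynamics`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle", "distance", "bond_angle", "dihedral",
    "place_atom", "pseudo_cbeta_direction", "kabsch_rotation", "kabsch_rmsd_np",
]


def wrap_angle(deg):
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped) if np.ndim(wrapped) else (
        180.0 if wrapped == -180.0 else float(wrapped))


def distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a, b, c, d, return_flag: bool = False):
    """Torsion angle a-b-c-d in degrees, in (-180, 180], IUPAC sign.

    Degenerate (colinear) geometries return 0.0; with ``return_flag=True``
    a second boolean marks that fallback.
    """
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(b2 / np.linalg.norm(b2), n1)
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return (0.0, True) if return_flag else 0.0
    ang = float(np.degrees(np.arctan2(y, x)))
    ang = 180.0 if ang == -180.0 else ang
    return (ang, False) if return_flag else ang


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d so that \\|c-d\\| = bond, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = torsion_deg (NeRF chaining)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def pseudo_cbeta_direction(n, ca, c, tetra_deg: float) -> np.ndarray:
    """Unit vector from CA toward the ideal tetrahedral C-beta position of an
    L-amino acid, computed from the backbone N, CA, C positions."""
    n, ca, c = (np.asarray(x, float) for x in (n, ca, c))
    u = n - ca
    u /= np.linalg.norm(u)
    v = c - ca
    v /= np.linalg.norm(v)
    cosuv = float(np.dot(u, v))
    ct = np.cos(np.radians(tetra_deg))
    alpha = ct / (1.0 + cosuv)
    resid = 1.0 - alpha * alpha * (2.0 + 2.0 * cosuv)
    beta = np.sqrt(max(resid, 0.0))
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)
    # sign of the out-of-plane component fixes the chirality (L-amino acids)
    direction = alpha * (u + v) + beta * normal
    return direction / np.linalg.norm(direction)


def kabsch_rotation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Proper rotation R (3x3) minimising \\|Xc @ R - Yc\\| over centred
    row-vector coordinate sets (reflections excluded via the SVD sign rule)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def kabsch_rmsd_np(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimal RMSD between point sets after optimal rigid superposition."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    R = kabsch_rotation(X, Y)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    diff = Xc @ R - Yc
    return float(np.sqrt((diff * diff).sum() / X.shape[0]))
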