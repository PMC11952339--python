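"""Low-level vector geometry: dihedrals, bond angles, rigid superposition, NeRF.

All functions operate on plain ``numpy`` arrays in Angstrom / degrees and are
vectorized over a leading batch dimension where noted.  Angles are wrapped to
the half-open interval (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "angular_difference",
    "dihedral",
    "bond_angle",
    "kabsch",
    "apply_rigid",
    "place_atom",
    "rotate_about_axis",
]


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -np.mod(-a + 180.0, 360.0) + 180.0
    return out


def angular_difference(a, b):
    """Shortest signed circular difference a - b in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(a, float) - np.asarray(b, float))


def _unit(v, axis=-1):
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.where(n == 0.0, 1.0, n)


def dihedral(p0, p1, p2, p3, degrees: bool = True):
    """Signed torsion angle of four points (IUPAC sign convention).

    Accepts arrays of shape (..., 3); returns shape (...).
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.arctan2(y, x)
    if degrees:
        return wrap_angle(np.degrees(ang))
    return ang


def bond_angle(p0, p1, p2, degrees: bool = True):
    """Angle at vertex p1 formed by p0-p1-p2, shapes (..., 3)."""
    p0, p1, p2 = (np.asarray(p, float) for p in (p0, p1, p2))
    u = _unit(p0 - p1)
    v = _unit(p2 - p1)
    c = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    ang = np.arccos(c)
    return np.degrees(ang) if degrees else ang


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation + translation mapping ``mobile`` onto ``reference``.

    Least-squares rigid superposition (no reflection).  Both inputs are (N, 3)
    with N >= 3.  Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t``
    minimizes the RMSD to ``reference``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch expects two (N, 3) arrays of equal shape")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    X = mobile - mu_m
    Y = reference - mu_r
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    moved = X @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Y) ** 2, axis=1))))
    return R, t, rmsd


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply rotation ``R`` and translation ``t`` to an (N, 3) array."""
    return np.asarray(coords, float) @ np.asarray(R, float).T + np.asarray(t, float)


def place_atom(a, b, c, bond_length: float, angle_deg: float, dihedral_deg: float):
    """NeRF placement: position a new atom D given three reference atoms.

    D is placed at ``bond_length`` from ``c``, with angle B-C-D equal to
    ``angle_deg`` and torsion A-B-C-D equal to ``dihedral_deg``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), -np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotate_about_axis(coords: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis`` (Rodrigues)."""
    coords = np.asarray(coords, float)
    origin = np.asarray(origin, float)
    k = _unit(np.asarray(axis, float))
    th = np.radians(angle_deg)
    p = coords - origin
    rot = (
        p * np.cos(th)
        + np.cross(k, p) * np.sin(th)
        + np.outer(p @ k, k) * (1.0 - np.cos(th))
    )
    return rot + origin
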