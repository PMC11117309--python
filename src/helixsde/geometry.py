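"""Low-level vector geometry: torsions, bond angles, internal-coordinate atom
placement (NeRF) and least-squares rigid superposition.

All functions take and return plain numpy arrays in Angstroms; angles are in
radians here — degree conversion happens at I/O boundaries only.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "kabsch",
    "rmsd_static",
]

_COLLINEAR_TOL = 1e-8


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in radians, in (-pi, pi].

    IUPAC sign convention: looking from p2 toward p3, the angle is positive
    when p4 is rotated clockwise relative to p1 (right-handed about p2->p3).
    Raises ``ValueError`` when three consecutive points are collinear, which
    leaves the torsion undefined.
    """
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    b3 = np.asarray(p4, dtype=float) - np.asarray(p3, dtype=float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    if n1n < _COLLINEAR_TOL or n2n < _COLLINEAR_TOL:
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = float(np.arctan2(y, x))
    # arctan2 returns (-pi, pi]; map -pi to +pi for a unique representative
    if ang <= -np.pi + 1e-15:
        ang = np.pi
    return ang


def bond_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Interior angle at p2, in radians, in [0, pi]."""
    v1 = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    l1 = np.linalg.norm(v1)
    l2 = np.linalg.norm(v2)
    if l1 < _COLLINEAR_TOL or l2 < _COLLINEAR_TOL:
        raise ValueError("bond angle undefined: zero-length arm")
    c = float(np.dot(v1, v2) / (l1 * l2))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    length: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D given three reference atoms so that |CD| = ``length``,
    the angle B-C-D equals ``angle`` and the torsion A-B-C-D equals
    ``torsion`` (both radians). Standard natural-extension (NeRF) step.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise ValueError("cannot place atom: reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(angle),
            length * np.sin(angle) * np.cos(torsion),
            -length * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of point set P onto Q (row correspondence).

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det = +1; a
    reflection in the SVD solution is corrected by flipping the smallest
    singular direction) and ``t`` the translation such that ``P @ R.T + t``
    best fits Q in the least-squares sense.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch requires matched n x 3 coordinate arrays")
    if P.shape[0] < 3:
        raise ValueError("kabsch requires at least 3 points")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P - pc) @ R.T + qc - Q
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return R, t, rmsd


def rmsd_static(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD without superposition (coordinates compared as-is)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(((P - Q) ** 2).sum() / P.shape[0]))
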