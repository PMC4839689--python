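"""Geometric primitives: distances, angles, torsions, internal-coordinate
atom placement, and least-squares rigid superposition.

All coordinates are in Å, all angles in degrees. Torsions follow the IUPAC
sign convention and are reported in the half-open interval (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance",
    "angle",
    "dihedral",
    "place_atom",
    "ideal_cb",
    "kabsch_superpose",
    "apply_transform",
    "random_rotation",
]

_COLLINEAR_TOL = 1e-10


def distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two points in Å."""
    return float(np.linalg.norm(np.asarray(q, float) - np.asarray(p, float)))


def angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Bond angle p1-p2-p3 in degrees, in [0, 180]."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COLLINEAR_TOL or nv < _COLLINEAR_TOL:
        raise ValueError("degenerate angle: coincident points")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle of the four points, in degrees, in (-180, 180].

    The angle is measured looking down the p2->p3 axis: positive when the
    far bond (p3->p4) is rotated clockwise relative to the near bond
    (p2->p1). A trans (anti-periplanar) arrangement gives 180, cis gives 0.

    Raises ValueError when either bonded triple is collinear (the torsion
    is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _COLLINEAR_TOL:
        raise ValueError("degenerate torsion: central bond has zero length")
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise ValueError("degenerate torsion: collinear frame")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / nb2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d bonded to c with |c-d| = bond_length, angle(b,c,d) =
    bond_angle and dihedral(a,b,c,d) = torsion (degrees).

    The natural-extension (NeRF) construction used to grow chains from
    internal coordinates.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise ValueError("collinear reference frame for atom placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(chi),
            bond_length * np.sin(theta) * np.sin(chi),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


# Idealized Cβ construction from backbone N/Cα/C. The fixed linear
# combination encodes the tetrahedral geometry and L-chirality of a
# standard amino acid; it reproduces |Cα-Cβ| ≈ 1.52 Å and
# angle(N, Cα, Cβ) ≈ 110°.
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized Cβ position for a residue given its backbone N, Cα, C."""
    n, ca, c = (np.asarray(p, float) for p in (n, ca, c))
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    k1, k2, k3 = _CB_COEFF
    return k1 * a + k2 * b + k3 * cc + ca


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of `mobile` onto `reference`.

    Parameters
    ----------
    mobile, reference : (n, 3) arrays of paired points, n >= 3.

    Returns
    -------
    rotation : (3, 3) proper rotation matrix (det = +1; reflections are
        disallowed, as required for chiral molecules).
    translation : (3,) vector.
    rmsd : root-mean-square deviation in Å after applying the transform,
        i.e. of ``mobile @ rotation.T + translation`` against `reference`.
    """
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    if p.shape != q.shape:
        raise ValueError(f"point count mismatch: {p.shape} vs {q.shape}")
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 3:
        raise ValueError("superposition requires at least 3 paired 3-D points")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to an (n, 3) coordinate array."""
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + np.asarray(
        translation, float
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation matrix (via QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
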