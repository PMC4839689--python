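"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library code:
superposition RMSD via Horn's quaternion eigenvalue method (the library
uses Kabsch/SVD) and torsions via the projection formula (the library
uses the double-cross-product formula).
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via the Horn quaternion method."""
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    gp = float(np.sum(pc**2))
    gq = float(np.sum(qc**2))
    return float(np.sqrt(max(0.0, (gp + gq - 2.0 * lam) / len(p))))


def projection_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle via projection onto the plane normal to the central bond."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    u1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, u1) * u1
    w = b2 - np.dot(b2, u1) * u1
    x = np.dot(v, w)
    y = np.dot(np.cross(u1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang
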