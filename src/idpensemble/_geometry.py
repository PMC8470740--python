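"""Internal vector-geometry helpers: torsions, internal-coordinate atom
placement (NeRF) and batched Kabsch superposition."""

from __future__ import annotations

import numpy as np


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle (degrees, in (−180, 180]) for points of shape
    (..., 3), IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so angles live in (−180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def bond_angle(p0, p1, p2) -> np.ndarray:
    """Angle at p1 in degrees for points of shape (..., 3)."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A, B, C such that |CD| = bond, angle(BCD) = angle
    and torsion(ABCD) = torsion (degrees).  Natural-extension (NeRF) step."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrices aligning centred P onto centred Q.

    P, Q of shape (..., n_atoms, 3); returns rotations R of shape
    (..., 3, 3) such that P @ R best matches Q (least squares).
    """
    H = np.einsum("...ni,...nj->...ij", P, Q)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("...ij,...jk->...ik", U, Vt)))
    # reflect the smallest singular direction where det < 0
    U = U.copy()
    U[..., :, -1] *= d[..., None]
    return np.einsum("...ij,...jk->...ik", U, Vt)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose frames (F, A, 3) onto a reference (A, 3).

    Returns the rotated+translated frames; unweighted Kabsch fit.
    """
    ref = reference - reference.mean(axis=0)
    cen = mobile - mobile.mean(axis=1, keepdims=True)
    R = kabsch_rotation(cen, ref[None])
    return np.einsum("fai,fij->faj", cen, R)


def rmsd_to_reference(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Minimal (superposed) RMSD of each frame (F, A, 3) to reference (A, 3)."""
    aligned = superpose(frames, reference)
    ref = reference - reference.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=2), axis=1))
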