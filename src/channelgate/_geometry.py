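"""Shared rigid-body and internal-coordinate geometry helpers.

All coordinates are in angstroms; angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kabsch",
    "rotation_angle_deg",
    "dihedral_deg",
    "place_atom",
    "amide_hydrogen",
]


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best matches
    ``reference``.  ``R`` is a proper rotation (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    if len(mobile) < 3:
        raise ValueError("need at least 3 point pairs for superposition")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    diff = mobile @ R.T + t - reference
    rmsd = float(np.sqrt((diff**2).sum() / len(mobile)))
    return R, t, rmsd


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a 3x3 rotation matrix, in [0, 180] degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3, wrapped to (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral_deg_frames(p0, p1, p2, p3) -> np.ndarray:
    """Vectorised dihedral over leading axes; inputs (..., 3)."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D given internal coordinates relative to chain a-b-c.

    ``bond`` = |c-D|, ``angle`` = angle(b, c, D) in degrees, ``dihedral`` =
    dihedral(a, b, c, D) in degrees (NeRF construction).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        -bond * np.sin(ang) * np.sin(dih),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def amide_hydrogen(n_pos: np.ndarray, prev_c: np.ndarray, ca_pos: np.ndarray,
                   bond: float = 1.01) -> np.ndarray:
    """Reconstruct the backbone amide H on N from C(prev) and CA.

    The H lies in the C-N-CA plane along the external bisector of the
    C-N-CA angle (standard geometric reconstruction for trans peptides).
    """
    n_pos, prev_c, ca_pos = (np.asarray(x, float) for x in (n_pos, prev_c, ca_pos))
    u = n_pos - prev_c
    u /= np.linalg.norm(u)
    v = n_pos - ca_pos
    v /= np.linalg.norm(v)
    h_dir = u + v
    nrm = np.linalg.norm(h_dir)
    if nrm < 1e-8:
        raise ValueError("degenerate backbone geometry at amide nitrogen")
    return n_pos + bond * h_dir / nrm


def sp2_amide_hydrogens(n_pos: np.ndarray, stem: np.ndarray, plane_ref: np.ndarray,
                        bond: float = 1.01) -> list[np.ndarray]:
    """Two H positions on an sp2 side-chain amide nitrogen (ASN ND2 / GLN NE2).

    ``stem`` is the carbon bonded to N (CG/CD); ``plane_ref`` a third atom
    defining the amide plane (OD1/OE1).  The hydrogens complete trigonal
    geometry at 120 degrees from the stem, in the amide plane.
    """
    n_pos, stem, plane_ref = (np.asarray(x, float) for x in (n_pos, stem, plane_ref))
    u = n_pos - stem
    u /= np.linalg.norm(u)
    w = plane_ref - stem
    n_axis = np.cross(u, w)
    n_axis /= np.linalg.norm(n_axis)
    m = np.cross(n_axis, u)
    out = []
    for sign in (+1.0, -1.0):
        d = np.cos(np.radians(60.0)) * u + sign * np.sin(np.radians(60.0)) * m
        out.append(n_pos + bond * d)
    return out


def angle_deg(a, b, c) -> float:
    """Angle at vertex b, in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
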