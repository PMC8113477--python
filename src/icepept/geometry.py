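"""Shared geometric primitives: minimum-image distances, dihedrals, Kabsch RMSD.

All coordinates are in Å; boxes are orthorhombic (lengths along x, y, z).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def min_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vector(s)."""
    if box is None:
        return vec
    box = np.asarray(box, dtype=float)
    return vec - box * np.round(vec / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image Euclidean distance between points (broadcasting over rows)."""
    return np.linalg.norm(min_image(np.asarray(a, float) - np.asarray(b, float), box), axis=-1)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention (cis/eclipsed = 0°).

    Looking from p1 towards p2, the angle is positive when the far bond
    (p2→p3) is rotated clockwise relative to the near bond (p1→p0).
    Returns NaN when the central atoms are collinear (angle undefined).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        return float("nan")
    b1u = b1 / nb1
    # components perpendicular to the central bond
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        return float("nan")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 into +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral_series(p0, p1, p2, p3) -> np.ndarray:
    """Vectorized signed dihedral over stacked frames, degrees in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1u = b1 / nb1
        v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
        w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
        x = np.sum(v * w, axis=-1)
        y = np.sum(np.cross(b1u, v) * w, axis=-1)
        ang = np.degrees(np.arctan2(y, x))
    bad = (
        (nb1[..., 0] < 1e-10)
        | (np.linalg.norm(v, axis=-1) < 1e-10)
        | (np.linalg.norm(w, axis=-1) < 1e-10)
    )
    ang = np.where(bad, np.nan, ang)
    return np.where(ang <= -180.0, ang + 360.0, ang)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates and the RMSD after
    superposition.  Uses the Kabsch algorithm (via quaternion SVD in
    :func:`scipy.spatial.transform.Rotation.align_vectors`); the rotation is
    proper (determinant +1), so mirror images are not matched.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("superpose: coordinate shapes differ")
    if mobile.shape[0] < 3:
        raise ValueError("superpose needs at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    moved = rot.apply(mobile - mc) + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rmsd


def rmsd(a: np.ndarray, b: np.ndarray, superpose_first: bool = False) -> float:
    """Root-mean-square deviation between two conformations of the same atoms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rmsd: coordinate shapes differ")
    if superpose_first:
        return superpose(a, b)[1]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def place_fourth_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                      bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given A, B, C, the C–D bond length, B–C–D angle and
    A–B–C–D dihedral (NeRF construction, consistent with :func:`dihedral`)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    # local frame: x along bc, y along m, z along n
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d_local
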