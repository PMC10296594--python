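"""Vector primitives on C-alpha coordinates.

All angles are in degrees: interior and vector angles in [0, 180],
torsions signed in (-180, 180] with the IUPAC convention (right-handed
rotations positive).  Distances are in the units of the input
coordinates (angstroms throughout this package).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "interior_angle",
    "torsion_angle",
    "vector_angle",
    "axis_distance",
    "point_segment_distance",
    "random_rotation",
]

_EPS = 1e-12


class InvalidGeometryError(ValueError):
    """Raised when a geometric quantity is undefined (degenerate input)."""


def _as_vec(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise InvalidGeometryError(f"expected a 3-vector, got shape {a.shape}")
    return a


def interior_angle(p, q, r) -> float:
    """Interior angle at ``q`` of the triangle ``(p, q, r)``, degrees."""
    p, q, r = _as_vec(p), _as_vec(q), _as_vec(r)
    u, v = p - q, r - q
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise InvalidGeometryError("zero-length arm in interior_angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def vector_angle(u, v) -> float:
    """Angle between two 3-vectors, degrees in [0, 180]."""
    u, v = _as_vec(u), _as_vec(v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise InvalidGeometryError("zero vector in vector_angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def torsion_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral of four points, degrees in (-180, 180].

    The angle between the plane through (p1, p2, p3) and the plane
    through (p2, p3, p4), measured about the p2->p3 axis; right-handed
    rotations are positive (matches mdtraj/MDAnalysis conventions).
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.linalg.norm(b1)
    if n1 < _EPS:
        raise InvalidGeometryError("coincident central points in torsion_angle")
    b1 = b1 / n1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _EPS or np.linalg.norm(w) < _EPS:
        raise InvalidGeometryError("collinear triple in torsion_angle")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    # normalize -180 -> +180 so the range is (-180, 180]
    return 180.0 if ang <= -180.0 + 1e-9 else ang


def _project_on_line(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = np.dot(ab, ab)
    if denom < _EPS:
        raise InvalidGeometryError("degenerate axis (coincident endpoints)")
    t = np.dot(p - a, ab) / denom
    return a + t * ab


def axis_distance(axis_a, axis_b, from_pt, to_pt, project_from: bool, project_to: bool) -> float:
    """Distance between two points measured relative to a virtual axis.

    The axis is the infinite line through ``axis_a`` and ``axis_b``.
    Each endpoint of the measured pair is either used as-is or replaced
    by its orthogonal projection onto the axis, per the two flags.
    """
    a, b = _as_vec(axis_a), _as_vec(axis_b)
    f, t = _as_vec(from_pt), _as_vec(to_pt)
    if project_from:
        f = _project_on_line(f, a, b)
    if project_to:
        t = _project_on_line(t, a, b)
    return float(np.linalg.norm(f - t))


def point_segment_distance(p, a, b) -> tuple[float, bool]:
    """Distance from ``p`` to the line through ``a``,``b`` plus a flag.

    Returns ``(distance, inside)`` where ``distance`` is measured to the
    infinite line and ``inside`` is True iff the foot of the
    perpendicular lies within the segment [a, b].
    """
    p, a, b = _as_vec(p), _as_vec(a), _as_vec(b)
    ab = b - a
    denom = np.dot(ab, ab)
    if denom < _EPS:
        raise InvalidGeometryError("degenerate segment (a == b)")
    t = float(np.dot(p - a, ab) / denom)
    foot = a + t * ab
    return float(np.linalg.norm(p - foot)), 0.0 <= t <= 1.0


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
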