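"""Small 2D geometry helpers shared by the landmark constructions.

All coordinates are image pixels: origin top-left, x right, y down,
sub-pixel values allowed.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

_EPS = 1e-12


def segment_intersection(p1, p2, q1, q2, tol: float = 1e-9):
    """Intersection point of segments p1-p2 and q1-q2.

    Solves the 2x2 linear system p1 + t(p2-p1) = q1 + u(q2-q1) and
    requires t, u in [0, 1] (within ``tol``), i.e. the segments must
    actually cross.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    d1 = p2 - p1
    d2 = q2 - q1
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < _EPS * max(1.0, np.abs(d1).max() * np.abs(d2).max()):
        raise GeometryError("segments are parallel or degenerate; no unique intersection")
    r = q1 - p1
    t = (r[0] * d2[1] - r[1] * d2[0]) / denom
    u = (r[0] * d1[1] - r[1] * d1[0]) / denom
    if not (-tol <= t <= 1 + tol and -tol <= u <= 1 + tol):
        raise GeometryError(
            f"segments do not intersect within their extents (t={t:.3f}, u={u:.3f})"
        )
    return p1 + t * d1


def line_ray_intersection(origin, direction, a, b):
    """Point where the ray origin + s*direction (s >= 0) meets the
    infinite line through a, b. Raises GeometryError if parallel or
    behind the origin."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d2 = b - a
    denom = direction[0] * d2[1] - direction[1] * d2[0]
    if abs(denom) < _EPS:
        raise GeometryError("ray is parallel to the line")
    r = a - origin
    s = (r[0] * d2[1] - r[1] * d2[0]) / denom
    if s < 0:
        raise GeometryError("line lies behind the ray origin")
    return origin + s * direction


def point_segment_distance(points, a, b):
    """Euclidean distance from points (..., 2) to segment a-b (vectorised)."""
    points = np.asarray(points, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b - a
    L2 = float(d @ d)
    if L2 < _EPS:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip(((points - a) @ d) / L2, 0.0, 1.0)
    proj = a + t[..., None] * d
    return np.linalg.norm(points - proj, axis=-1)


def unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < _EPS:
        raise GeometryError("zero-length vector cannot be normalised")
    return v / n


def perp(v):
    """A vector perpendicular to v (rotated +90 degrees)."""
    v = np.asarray(v, dtype=float)
    return np.array([-v[1], v[0]])


def signed_line_distance(points, a, b, normal_hint):
    """Signed perpendicular distance of points to the infinite line a-b,
    positive on the side of ``normal_hint``."""
    points = np.asarray(points, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = perp(unit(b - a))
    if float(n @ np.asarray(normal_hint, dtype=float)) < 0:
        n = -n
    return (points - a) @ n
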