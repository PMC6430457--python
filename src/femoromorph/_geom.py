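"""Low-level vector geometry and least-squares primitives.

Pure numpy; no domain types.  Points are float64 arrays of shape (3,) or
(n, 3), all in millimetres.
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    """Normalise a vector; raises on (near-)zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    c = float(np.dot(unit(a), unit(b)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def point_line_distance(p: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    """Euclidean distance from point(s) ``p`` to the line (origin, direction)."""
    d = unit(direction)
    rel = np.atleast_2d(p) - origin
    perp = rel - np.outer(rel @ d, d)
    out = np.linalg.norm(perp, axis=1)
    return float(out[0]) if np.ndim(p) == 1 else out


def project_point_on_line(p: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    d = unit(direction)
    return origin + np.dot(p - origin, d) * d


def point_line_distance_2d(p: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    """Distance from a 2-D point to a 2-D line; falls back to the point
    distance when the direction vanishes (line projects to a point)."""
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if n < 1e-9:
        return float(np.linalg.norm(p - origin))
    d = direction / n
    rel = p - origin
    return float(np.abs(rel[0] * d[1] - rel[1] * d[0]))


def fit_line_tls(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares 3-D line through a point cloud.

    Returns (centroid, unit direction); the direction is the first principal
    axis of the centred points, with arbitrary sign.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two points for a line fit")
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    return c, vt[0]


def fit_sphere_algebraic(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear least-squares sphere fit (Coope's method).

    Solves ``|x|^2 = 2 c.x + (r^2 - |c|^2)`` for centre c and radius r.
    Exact for noise-free spherical data, including partial caps.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least four points for a sphere fit")
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate sphere fit")
    return center, float(np.sqrt(r2))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    k = unit(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def orthonormal_basis_perp(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the plane perpendicular to ``d``."""
    d = unit(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(d, helper))
    e2 = np.cross(d, e1)
    return e1, e2
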