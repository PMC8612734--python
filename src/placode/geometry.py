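"""Polygon geometry primitives shared across the package.

All coordinates are in micrometres, polygons are closed counter-clockwise
vertex lists (the closing vertex is *not* repeated).  The equivalent-moment
ellipse of a polygon is the ellipse with the same area and the same second
order area moments; its semi-axes are ``2*sqrt(eigenvalues)`` of the
area-normalised covariance matrix, the region-analysis convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "polygon_area",
    "polygon_centroid",
    "polygon_covariance",
    "ensure_ccw",
    "moments_ellipse",
    "ellipse_shape_tensor",
    "wrap_angle",
]


def _cross_terms(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = np.asarray(poly, dtype=float)
    q = np.roll(p, -1, axis=0)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    return p, q, cross


def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area (positive for counter-clockwise polygons)."""
    _, _, cross = _cross_terms(poly)
    return 0.5 * float(np.sum(cross))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    p, q, cross = _cross_terms(poly)
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-300:
        return np.mean(p, axis=0)
    cx = np.sum((p[:, 0] + q[:, 0]) * cross) / (6.0 * a)
    cy = np.sum((p[:, 1] + q[:, 1]) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_covariance(poly: np.ndarray) -> np.ndarray:
    """Area-normalised second central moments (2x2 covariance matrix)."""
    p, q, cross = _cross_terms(poly)
    a = 0.5 * np.sum(cross)
    c = polygon_centroid(poly)
    # second moments about the origin
    ixx = np.sum((p[:, 0] ** 2 + p[:, 0] * q[:, 0] + q[:, 0] ** 2) * cross) / 12.0
    iyy = np.sum((p[:, 1] ** 2 + p[:, 1] * q[:, 1] + q[:, 1] ** 2) * cross) / 12.0
    ixy = np.sum(
        (p[:, 0] * q[:, 1] + 2 * p[:, 0] * p[:, 1] + 2 * q[:, 0] * q[:, 1] + q[:, 0] * p[:, 1])
        * cross
    ) / 24.0
    cov = np.array([[ixx, ixy], [ixy, iyy]]) / a - np.outer(c, c)
    return cov


def ensure_ccw(poly: np.ndarray) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    if polygon_area(poly) < 0:
        return poly[::-1].copy()
    return poly


def moments_ellipse(poly: np.ndarray) -> tuple[float, float, float]:
    """Equivalent-moment ellipse of a polygon.

    Returns ``(major, minor, phi)`` where major/minor are the *semi*-axis
    lengths in µm and ``phi`` is the major-axis orientation in radians,
    reduced to ``[0, pi)``.
    """
    cov = polygon_covariance(poly)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order
    minor = 2.0 * np.sqrt(max(evals[0], 0.0))
    major = 2.0 * np.sqrt(max(evals[1], 0.0))
    v = evecs[:, 1]
    phi = float(np.arctan2(v[1], v[0])) % np.pi
    return float(major), float(minor), phi


def ellipse_shape_tensor(major: float, minor: float, phi: float) -> np.ndarray:
    """Symmetric shape tensor R diag(a^2, b^2) R^T of an ellipse."""
    c, s = np.cos(phi), np.sin(phi)
    r = np.array([[c, -s], [s, c]])
    return r @ np.diag([major**2, minor**2]) @ r.T


def wrap_angle(angle: float, period: float = 2 * np.pi) -> float:
    """Wrap an angle into [0, period)."""
    return float(angle % period)
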