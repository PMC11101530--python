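"""Brute-force geometric oracles, independent of the package implementation.

Everything here recomputes shape descriptors from raw pixel coordinate
sets using elementary methods: explicit second-moment sums with a
closed-form 2x2 eigen solution, a monotone-chain convex hull with the
shoelace area, and O(n^2) pairwise distances over pixel-square corners.
"""

from __future__ import annotations

import math

import numpy as np


def corner_points(pixels: np.ndarray) -> np.ndarray:
    """Unique corner points of the pixel squares (pixel centres ± 0.5)."""
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (np.asarray(pixels, dtype=float)[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    return np.unique(pts, axis=0)


def hull_monotone_chain(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices (counter-clockwise) by Andrew's monotone chain."""
    pts = sorted(map(tuple, np.asarray(points, dtype=float)))
    if len(pts) <= 2:
        return np.asarray(pts)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.asarray(lower[:-1] + upper[:-1])


def shoelace_area(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def brute_elongation(pixels: np.ndarray) -> float:
    """Variance ratio along/across the principal axis via closed-form 2x2 eigen."""
    p = np.asarray(pixels, dtype=float)
    p = p - p.mean(axis=0)
    sxx = float((p[:, 0] ** 2).sum()) / len(p)
    syy = float((p[:, 1] ** 2).sum()) / len(p)
    sxy = float((p[:, 0] * p[:, 1]).sum()) / len(p)
    half_tr = 0.5 * (sxx + syy)
    disc = math.sqrt((0.5 * (sxx - syy)) ** 2 + sxy**2)
    lam_max, lam_min = half_tr + disc, half_tr - disc
    if lam_min <= 1e-9:
        raise ValueError("degenerate pixel set")
    return lam_max / lam_min


def brute_solidity(pixels: np.ndarray) -> float:
    hull = hull_monotone_chain(corner_points(pixels))
    return len(pixels) / shoelace_area(hull)


def brute_feret(pixels: np.ndarray, calibration: float = 1.0) -> float:
    """Max pairwise distance over all pixel-square corners (no hull shortcut)."""
    c = corner_points(pixels)
    diff = c[:, None, :] - c[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max() * calibration)


def rasterize_ellipse(a: float, b: float, angle: float = 0.0) -> np.ndarray:
    """Pixel centres inside an ellipse with semi-axes a, b rotated by angle."""
    half = int(math.ceil(max(a, b))) + 1
    ax = np.arange(-half, half + 1, dtype=float)
    x, y = np.meshgrid(ax, ax)
    ca, sa = math.cos(angle), math.sin(angle)
    u = (ca * x + sa * y) / a
    v = (-sa * x + ca * y) / b
    rr, cc = np.nonzero(u**2 + v**2 <= 1.0)
    return np.column_stack((rr, cc))
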