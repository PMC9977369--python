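"""Brute-force reference implementations for validating the geometry stack.

Deliberately independent of the production code paths: Monte-Carlo hit
counting instead of the shoelace/clipping machinery, fan triangulation for
centroids, exhaustive O(n^2) pairwise search for the Feret diameter, and a
crossing-number (even-odd ray casting) point-in-polygon test. Slow but
simple; used in tests and calibration experiments as independent oracles.
"""

from __future__ import annotations

import numpy as np

from .model import Region


def _crossings(xy: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Even-odd rule: is each point inside the closed ring (boundary excluded)."""
    x, y = xy[:, 0], xy[:, 1]
    inside = np.zeros(len(xy), dtype=bool)
    x1, y1 = ring[:, 0], ring[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for xa, ya, xb, yb in zip(x1, y1, x2, y2):
        crosses = (ya > y) != (yb > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = xa + (y - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (x < xint)
    return inside


def ray_casting_inside(region: Region, xy: np.ndarray) -> np.ndarray:
    """Crossing-number point-in-region test (inside outer, outside holes)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    inside = _crossings(xy, region.outer)
    for hole in region.holes:
        inside &= ~_crossings(xy, hole)
    return inside


def monte_carlo_area(region: Region, rng: np.random.Generator,
                     n: int = 1_000_000) -> tuple[float, float]:
    """Rejection-sampling area estimate (nm^2) and its standard error."""
    minx, miny = region.outer.min(axis=0)
    maxx, maxy = region.outer.max(axis=0)
    pts = np.column_stack([rng.uniform(minx, maxx, n),
                           rng.uniform(miny, maxy, n)])
    hit = ray_casting_inside(region, pts)
    p = hit.mean()
    bbox = (maxx - minx) * (maxy - miny)
    return p * bbox, bbox * np.sqrt(p * (1 - p) / n)


def _fan_centroid(ring: np.ndarray) -> tuple[float, float, float]:
    """Signed area and centroid of a simple polygon by fan triangulation."""
    o = ring[0]
    area = 0.0
    cx = cy = 0.0
    for a, b in zip(ring[1:-1], ring[2:]):
        s = 0.5 * ((a[0] - o[0]) * (b[1] - o[1]) - (b[0] - o[0]) * (a[1] - o[1]))
        c = (o + a + b) / 3.0
        area += s
        cx += s * c[0]
        cy += s * c[1]
    return area, cx, cy


def triangulation_centroid(region: Region) -> tuple[float, float]:
    """Area-weighted centroid via fan triangulation, holes subtracting."""
    area, cx, cy = _fan_centroid(region.outer)
    sign = 1.0 if area > 0 else -1.0
    area, cx, cy = sign * area, sign * cx, sign * cy
    for hole in region.holes:
        ha, hx, hy = _fan_centroid(hole)
        hs = 1.0 if ha > 0 else -1.0
        area -= hs * ha
        cx -= hs * hx
        cy -= hs * hy
    return cx / area, cy / area


def brute_force_feret(vertices: np.ndarray) -> float:
    """Maximum pairwise vertex distance by exhaustive O(n^2) search."""
    best = 0.0
    for i in range(len(vertices) - 1):
        d = np.hypot(*(vertices[i + 1:] - vertices[i]).T)
        best = max(best, float(d.max()))
    return best
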