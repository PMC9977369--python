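"""Planar geometry of PSD contours.

Area, center of gravity (area centroid), maximum Feret (caliper) diameter,
pose normalization onto a canonical frame, and synaptic/extra-synaptic
classification of gold grains.

The canonical pose places the center of gravity at the origin and rotates the
contour so the maximum-Feret vertex pair lies on the horizontal axis. Because
a line is invariant under rotation by pi, the rotation is only defined modulo
pi; we fix it to [0, pi) and apply no reflection, so averaged maps retain a
180-degree ambiguity per PSD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy.spatial import ConvexHull

from .model import Particle, PSDRecord, Region

NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class Pose:
    """Rigid motion: translate by ``translation`` (nm), then rotate by
    ``rotation`` radians about the origin. ``rotation`` lies in [0, pi)."""

    translation: tuple[float, float]
    rotation: float

    def __post_init__(self):
        if not (0.0 <= self.rotation < np.pi):
            raise ValueError(f"rotation must lie in [0, pi), got {self.rotation}")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float) + np.asarray(self.translation)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        return xy @ rot.T


def region_area(r: Region) -> float:
    """Region area in um^2 (outer minus holes); 1 um^2 = 1e6 nm^2."""
    area_nm2 = r.to_polygon().area
    if area_nm2 <= 0:
        raise ValueError("degenerate region: zero area")
    return area_nm2 / NM2_PER_UM2


def center_of_gravity(r: Region) -> tuple[float, float]:
    """Area-weighted centroid in nm (holes subtract).

    For ring- or horseshoe-shaped PSDs the centroid may fall outside the
    material region; it still lies inside the bounding box of the outer ring.
    """
    poly = r.to_polygon()
    if poly.area <= 0:
        raise ValueError("degenerate region: zero area")
    c = poly.centroid
    return (c.x, c.y)


def max_feret_diameter(r: Region) -> tuple[float, tuple[int, int]]:
    """Maximum Feret (caliper) diameter of the outer contour, in nm.

    Returns the diameter and the achieving pair of outer-vertex indices.
    Both endpoints of any diameter lie on the convex hull, so only hull
    vertices are searched; ties resolve to the lexicographically smallest
    index pair.
    """
    pts = r.outer
    if len(pts) < 3:
        raise ValueError("max_feret_diameter needs >= 3 vertices")
    try:
        idx = np.sort(ConvexHull(pts).vertices)
    except Exception:  # nearly collinear input: fall back to all vertices
        idx = np.arange(len(pts))
    best = -1.0
    best_pair = (0, 0)
    for a in range(len(idx)):
        i = idx[a]
        d = np.hypot(*(pts[idx[a + 1:]] - pts[i]).T)
        if d.size == 0:
            continue
        k = int(np.argmax(d))
        # strict > keeps the first (lexicographically smallest) pair on ties;
        # argmax already returns the smallest j for equal distances
        if d[k] > best:
            best = float(d[k])
            best_pair = (int(i), int(idx[a + 1 + k]))
    return best, best_pair


def transform_record(rec: PSDRecord, pose: Pose) -> PSDRecord:
    """Apply the same rigid motion to the contour, holes and particles."""
    outer = pose.apply(rec.region.outer)
    holes = tuple(pose.apply(h) for h in rec.region.holes)
    particles = tuple(
        replace(p, x=float(q[0]), y=float(q[1]))
        for p, q in zip(
            rec.particles,
            pose.apply(np.array([[p.x, p.y] for p in rec.particles]))
            if rec.particles else [],
        )
    )
    return replace(rec, region=Region(outer=outer, holes=holes), particles=particles)


def normalize_pose(rec: PSDRecord) -> tuple[PSDRecord, Pose]:
    """Rigidly move a record into the canonical frame.

    The center of gravity goes to (0, 0) and the maximum-Feret vertex pair
    onto the horizontal axis. Areas and pairwise distances are preserved.
    """
    cx, cy = center_of_gravity(rec.region)
    _, (i, j) = max_feret_diameter(rec.region)
    dx, dy = rec.region.outer[j] - rec.region.outer[i]
    theta = np.arctan2(dy, dx) % np.pi
    rotation = (-theta) % np.pi
    if rotation >= np.pi:  # guard against fp wrap at the boundary
        rotation = 0.0
    pose = Pose(translation=(-cx, -cy), rotation=rotation)
    return transform_record(rec, pose), pose


def points_in_region(r: Region, xy: np.ndarray) -> np.ndarray:
    """Boolean mask: which points lie in the material region.

    Boundary points (outer ring or hole rings) count as inside, matching the
    convention that grains on the traced contour are within the PSD.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    poly = r.to_polygon()
    shapely.prepare(poly)
    pts = shapely.points(xy[:, 0], xy[:, 1])
    return shapely.covers(poly, pts)


def classify_particles(rec: PSDRecord) -> tuple[list[Particle], list[Particle]]:
    """Partition particles into (synaptic, extra-synaptic).

    Synaptic means inside the outer contour and outside every hole (even-odd
    rule); boundary points are synaptic. Extra-synaptic grains are excluded
    from all downstream quantification.
    """
    if not rec.particles:
        return [], []
    xy = np.array([[p.x, p.y] for p in rec.particles])
    mask = points_in_region(rec.region, xy)
    synaptic = [p for p, m in zip(rec.particles, mask) if m]
    extra = [p for p, m in zip(rec.particles, mask) if not m]
    return synaptic, extra


def synaptic_count(rec: PSDRecord) -> int:
    """Number of grains within the contoured area."""
    return len(classify_particles(rec)[0])
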