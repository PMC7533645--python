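"""Locate the mesh triangles intersected by fiber extremities (Step 3).

Ray/triangle tests use the Möller-Trumbore algorithm; candidate triangles
come from a uniform grid over triangle bounding boxes, which is exact for
the configured search radius.  A two-phase strategy resolves each endpoint:
a directed ray from the penultimate point first, then a nearest-triangle
fallback within the search radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .data_model_io import LabeledSurface, PipelineConfig, Tractogram
from .bundle_segmentation import SegmentedFiber

log = logging.getLogger(__name__)

_DET_EPS = 1e-12
_BARY_EPS = 1e-9


@dataclass
class IntersectionRecord:
    fiber_id: int
    bundle_name: str
    tri_start: int
    tri_end: int


def moller_trumbore(origin: np.ndarray, direction: np.ndarray,
                    v0: np.ndarray, v1: np.ndarray, v2: np.ndarray
                    ) -> Optional[tuple[float, float, float]]:
    """Ray/triangle intersection; returns ``(t, u, v)`` or ``None`` on miss.

    Hits require |det| > 1e-12, barycentrics within 1e-9 slack of [0, 1]
    and ray parameter t >= -1e-9.
    """
    direction = np.asarray(direction, dtype=np.float64)
    if np.linalg.norm(direction) == 0.0:
        raise ValueError("ray direction must be non-zero")
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(direction, e2)
    det = float(np.dot(e1, pvec))
    if abs(det) <= _DET_EPS:
        return None
    inv_det = 1.0 / det
    tvec = origin - v0
    u = float(np.dot(tvec, pvec)) * inv_det
    if u < -_BARY_EPS:
        return None
    qvec = np.cross(tvec, e1)
    v = float(np.dot(direction, qvec)) * inv_det
    if v < -_BARY_EPS or u + v > 1.0 + _BARY_EPS:
        return None
    t = float(np.dot(e2, qvec)) * inv_det
    if t < -_BARY_EPS:
        return None
    return t, u, v


def closest_point_on_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                              c: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on triangle ``abc`` (Ericson, Real-Time CD)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = float(np.dot(ab, ap)), float(np.dot(ac, ap))
    if d1 <= 0.0 and d2 <= 0.0:
        return a
    bp = p - b
    d3, d4 = float(np.dot(ab, bp)), float(np.dot(ac, bp))
    if d3 >= 0.0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = float(np.dot(ab, cp)), float(np.dot(ac, cp))
    if d6 >= 0.0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        return b + ((d4 - d3) / ((d4 - d3) + (d5 - d6))) * (c - b)
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def point_triangle_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                            c: np.ndarray) -> float:
    return float(np.linalg.norm(p - closest_point_on_triangle(p, a, b, c)))


class TriangleGrid:
    """Uniform spatial hash over triangle axis-aligned bounding boxes.

    A box query returns every triangle whose AABB intersects the query box,
    so querying the endpoint box inflated by the search radius is a superset
    of all triangles within that radius — the acceleration is exact.
    """

    def __init__(self, surface: LabeledSurface, cell_size: Optional[float] = None):
        self.surface = surface
        tris = surface.vertices[surface.triangles]  # (nt, 3, 3)
        self.aabb_min = tris.min(axis=1)
        self.aabb_max = tris.max(axis=1)
        if cell_size is None:
            extents = self.aabb_max - self.aabb_min
            cell_size = max(float(np.median(extents.max(axis=1))) * 2.0, 1e-3)
        self.cell = cell_size
        self.cells: dict[tuple[int, int, int], list[int]] = {}
        for t in range(len(tris)):
            lo = np.floor(self.aabb_min[t] / self.cell).astype(int)
            hi = np.floor(self.aabb_max[t] / self.cell).astype(int)
            for ix in range(lo[0], hi[0] + 1):
                for iy in range(lo[1], hi[1] + 1):
                    for iz in range(lo[2], hi[2] + 1):
                        self.cells.setdefault((ix, iy, iz), []).append(t)

    def query_box(self, lo: np.ndarray, hi: np.ndarray) -> list[int]:
        ilo = np.floor(np.asarray(lo) / self.cell).astype(int)
        ihi = np.floor(np.asarray(hi) / self.cell).astype(int)
        found: set[int] = set()
        for ix in range(ilo[0], ihi[0] + 1):
            for iy in range(ilo[1], ihi[1] + 1):
                for iz in range(ilo[2], ihi[2] + 1):
                    found.update(self.cells.get((ix, iy, iz), ()))
        return sorted(found)

    def candidates_near(self, point: np.ndarray, radius: float) -> list[int]:
        """Triangles whose AABB lies within ``radius`` of ``point``."""
        point = np.asarray(point, dtype=np.float64)
        rough = self.query_box(point - radius, point + radius)
        out = []
        for t in rough:
            gap = np.maximum(self.aabb_min[t] - point, 0.0) \
                + np.maximum(point - self.aabb_max[t], 0.0)
            if float(np.linalg.norm(gap)) <= radius:
                out.append(t)
        return out


def locate_endpoint(fiber: np.ndarray, end: str, surface: LabeledSurface,
                    cfg: PipelineConfig, grid: Optional[TriangleGrid] = None
                    ) -> Optional[int]:
    """Triangle index intersected by one fiber extremity, or ``None``.

    Phase 1 casts a ray from the penultimate point through the endpoint and
    keeps hits landing at most ``ray_extension_mm`` beyond the endpoint;
    phase 2 falls back to the nearest triangle within ``endpoint_radius_mm``.
    """
    pts = np.asarray(fiber, dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("fiber needs at least 2 points")
    if end == "first":
        endpoint, penult = pts[0], pts[1]
    elif end == "last":
        endpoint, penult = pts[-1], pts[-2]
    else:
        raise ValueError(f"end must be 'first' or 'last', got {end!r}")
    if grid is None:
        grid = TriangleGrid(surface)
    r = cfg.endpoint_radius_mm
    eps = cfg.ray_extension_mm
    candidates = grid.candidates_near(endpoint, r)
    verts, tris = surface.vertices, surface.triangles

    direction = endpoint - penult
    norm = float(np.linalg.norm(direction))
    best: Optional[tuple[float, int]] = None
    if norm > 0.0:
        unit = direction / norm
        for t in candidates:
            a, b, c = verts[tris[t, 0]], verts[tris[t, 1]], verts[tris[t, 2]]
            hit = moller_trumbore(penult, unit, a, b, c)
            if hit is None:
                continue
            tval = hit[0]
            if tval > norm + eps:
                continue  # hit point too far beyond the endpoint
            hit_point = penult + tval * unit
            d = float(np.linalg.norm(hit_point - endpoint))
            if best is None or (d, t) < best:
                best = (d, t)
    if best is not None:
        return best[1]

    # phase 2: nearest triangle within the search radius
    for t in candidates:
        a, b, c = verts[tris[t, 0]], verts[tris[t, 1]], verts[tris[t, 2]]
        d = point_triangle_distance(endpoint, a, b, c)
        if d <= r and (best is None or (d, t) < best):
            best = (d, t)
    return None if best is None else best[1]


def intersect_tractogram(t: Tractogram, segmented: Iterable[SegmentedFiber],
                         surface: LabeledSurface, cfg: PipelineConfig,
                         grid: Optional[TriangleGrid] = None
                         ) -> list[IntersectionRecord]:
    """One record per segmented fiber with both extremities resolved.

    Fibers with any unresolved end are dropped; the count is logged.
    """
    if surface.n_triangles == 0:
        raise ValueError("empty surface")
    if grid is None:
        grid = TriangleGrid(surface)
    records: list[IntersectionRecord] = []
    dropped = 0
    for sf in segmented:
        pts = t.streamlines[sf.fiber_id].points
        tri_start = locate_endpoint(pts, "first", surface, cfg, grid)
        tri_end = locate_endpoint(pts, "last", surface, cfg, grid)
        if tri_start is None or tri_end is None:
            dropped += 1
            continue
        records.append(IntersectionRecord(
            fiber_id=sf.fiber_id, bundle_name=sf.bundle_name,
            tri_start=tri_start, tri_end=tri_end))
    if dropped:
        log.info("intersect_tractogram: dropped %d fibers with unresolved ends", dropped)
    return records
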