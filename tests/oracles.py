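"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths they check: plane-equation ray
casting instead of Möller-Trumbore, per-bundle python loops instead of the
stacked segmentation, subset enumeration instead of Bron-Kerbosch, and
explicit flood fill for components.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ray_triangle_plane_oracle(origin, direction, v0, v1, v2,
                              eps_det=1e-12, eps_bary=1e-9):
    """Closed-form plane intersection + barycentric sign test.

    Returns (t, u, v) or None, with the same tolerance contract as the
    Möller-Trumbore implementation.
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    n = np.cross(v1 - v0, v2 - v0)
    denom = float(np.dot(n, direction))
    if abs(denom) <= eps_det:
        return None
    t = float(np.dot(n, v0 - origin)) / denom
    if t < -eps_bary:
        return None
    p = origin + t * direction
    # barycentrics via the standard dot-product solve
    u_vec, v_vec, w_vec = v1 - v0, v2 - v0, p - v0
    d00 = float(np.dot(u_vec, u_vec))
    d01 = float(np.dot(u_vec, v_vec))
    d11 = float(np.dot(v_vec, v_vec))
    d20 = float(np.dot(w_vec, u_vec))
    d21 = float(np.dot(w_vec, v_vec))
    det = d00 * d11 - d01 * d01
    if det == 0.0:
        return None
    u = (d11 * d20 - d01 * d21) / det
    v = (d00 * d21 - d01 * d20) / det
    if u < -eps_bary or v < -eps_bary or u + v > 1.0 + eps_bary:
        return None
    return t, u, v


def segment_oracle(fiber_points, atlas):
    """Exhaustive all-pairs assignment for one fiber.

    Loops bundles and member fibers explicitly; returns
    (bundle_name, distance, flipped) or None.
    """
    best = None
    for bundle in sorted(atlas.bundles, key=lambda b: b.name):
        bd = None
        for f in bundle.fibers:
            dd = float(np.linalg.norm(fiber_points - f, axis=1).max())
            df = float(np.linalg.norm(fiber_points - f[::-1], axis=1).max())
            cand = (dd, False) if dd <= df else (df, True)
            if bd is None or cand[0] < bd[0]:
                bd = cand
        if bd is not None and bd[0] <= bundle.threshold_mm:
            if best is None or bd[0] < best[1]:
                best = (bundle.name, bd[0], bd[1])
    return best


def nearest_hit_oracle(fiber_points, end, surface, cfg):
    """Exhaustive all-triangle version of endpoint location."""
    from cortiparcel.mesh_intersection import (
        moller_trumbore, point_triangle_distance)

    pts = np.asarray(fiber_points, float)
    endpoint, penult = (pts[0], pts[1]) if end == "first" else (pts[-1], pts[-2])
    verts, tris = surface.vertices, surface.triangles
    direction = endpoint - penult
    norm = float(np.linalg.norm(direction))
    best = None
    if norm > 0.0:
        unit = direction / norm
        for t in range(len(tris)):
            a, b, c = verts[tris[t, 0]], verts[tris[t, 1]], verts[tris[t, 2]]
            gap = np.maximum(np.minimum.reduce([a, b, c]) - endpoint, 0.0) \
                + np.maximum(endpoint - np.maximum.reduce([a, b, c]), 0.0)
            if float(np.linalg.norm(gap)) > cfg.endpoint_radius_mm:
                continue
            hit = moller_trumbore(penult, unit, a, b, c)
            if hit is None or hit[0] > norm + cfg.ray_extension_mm:
                continue
            d = float(np.linalg.norm(penult + hit[0] * unit - endpoint))
            if best is None or (d, t) < best:
                best = (d, t)
    if best is not None:
        return best[1]
    for t in range(len(tris)):
        a, b, c = verts[tris[t, 0]], verts[tris[t, 1]], verts[tris[t, 2]]
        gap = np.maximum(np.minimum.reduce([a, b, c]) - endpoint, 0.0) \
            + np.maximum(endpoint - np.maximum.reduce([a, b, c]), 0.0)
        if float(np.linalg.norm(gap)) > cfg.endpoint_radius_mm:
            continue
        d = point_triangle_distance(endpoint, a, b, c)
        if d <= cfg.endpoint_radius_mm and (best is None or (d, t) < best):
            best = (d, t)
    return None if best is None else best[1]


def maximal_cliques_bruteforce(nodes, edges):
    """All maximal cliques by explicit subset enumeration (<= ~15 nodes)."""
    nodes = sorted(nodes)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset((a, b)) in edge_set for a, b in combinations(sub, 2))

    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if not is_clique(sub):
                continue
            if any(is_clique(sub + (x,)) for x in nodes if x not in sub):
                continue
            cliques.append(tuple(sub))
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def flood_fill_components(triangles_of_label, edge_adjacency):
    """Connected components by explicit BFS flood fill."""
    remaining = set(triangles_of_label)
    comps = []
    while remaining:
        start = min(remaining)
        queue = [start]
        comp = {start}
        remaining.discard(start)
        while queue:
            t = queue.pop(0)
            for nb in edge_adjacency[t]:
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def idc_oracle(sa, sb):
    """Set-overlap fraction via sorted-list merge (independent of set ops)."""
    if not sa or not sb:
        return 0.0
    la, lb = sorted(sa), sorted(sb)
    i = j = inter = 0
    while i < len(la) and j < len(lb):
        if la[i] == lb[j]:
            inter += 1
            i += 1
            j += 1
        elif la[i] < lb[j]:
            i += 1
        else:
            j += 1
    return inter / min(len(la), len(lb))


def dice_oracle(sa, sb):
    if not sa and not sb:
        return 0.0
    la, lb = sorted(sa), sorted(sb)
    i = j = inter = 0
    while i < len(la) and j < len(lb):
        if la[i] == lb[j]:
            inter += 1
            i += 1
            j += 1
        elif la[i] < lb[j]:
            i += 1
        else:
            j += 1
    return 2.0 * inter / (len(la) + len(lb))
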