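"""Fully-controlled synthetic cohorts: labeled sphere, bundle atlas with
ground-truth sub-parcel footprints, and multi-subject tractograms.

The cortex is an icosphere partitioned into edge-connected regions; every
region is subdivided into disjoint footprint patches.  Footprints are paired
into bundles whose fibers arc through the interior of the sphere between
random points of the two patches.  Subjects are the atlas fibers under
Gaussian jitter with random orientation flips, plus deep distractor fibers
guaranteed to fail every bundle threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .data_model_io import (
    Bundle,
    BundleAtlas,
    LabeledSurface,
    Streamline,
    Tractogram,
    read_labeled_surface,
    read_tractogram,
    resample_streamline,
    write_labeled_surface,
    write_tractogram,
)

N_POINTS = 21


# ---------------------------------------------------------------------------
# icosphere
# ---------------------------------------------------------------------------

def icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere: 10*4^k + 2 vertices, 20*4^k triangles."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=np.float64)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (vlist[a] + vlist[b]) / 2.0
                m /= np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return verts, faces


def _region_components_ok(surface: LabeledSurface, n_regions: int) -> bool:
    """Every region present, edge-connected at the triangle level, non-tiny."""
    for region in range(n_regions):
        tris = set(int(t) for t in surface.region_triangles(region))
        if len(tris) < 8:
            return False
        start = min(tris)
        seen = {start}
        stack = [start]
        while stack:
            t = stack.pop()
            for nb in surface.edge_adjacency[t]:
                if nb in tris and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != tris:
            return False
    return True


def make_labeled_sphere(subdivisions: int, n_regions: int, seed: int,
                        radius: float = 50.0,
                        max_tries: int = 200) -> LabeledSurface:
    """Icosphere whose vertices are partitioned into edge-connected regions.

    Regions are the nearest-seed partition from ``n_regions`` random unit
    vectors; seed sets are resampled until every region is edge-connected.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    verts, faces = icosphere(subdivisions)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seeds = rng.normal(size=(n_regions, 3))
        seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
        labels = np.argmax(verts @ seeds.T, axis=1).astype(np.int64)
        surface = LabeledSurface(vertices=verts * radius, triangles=faces,
                                 vertex_labels=labels)
        if _region_components_ok(surface, n_regions):
            return surface
    raise RuntimeError(f"could not produce {n_regions} connected regions "
                       f"in {max_tries} tries")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Footprint patches, bundle pairing and generation parameters.

    ``footprints`` are the expected cortical imprints of each bundle end
    (sampling core plus its one-ring neighborhood); ``sample_areas`` are the
    cores from which fiber endpoints are drawn.
    """

    footprints: dict[str, list[int]]                  # footprint id -> triangles
    footprint_region: dict[str, int]
    bundles: dict[str, tuple[str, str]]               # bundle name -> (fp_start, fp_end)
    region_hemisphere: dict[int, str]                 # region -> "left"|"right"
    sample_areas: dict[str, list[int]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def footprint_set(self, fid: str) -> set[int]:
        return set(self.footprints[fid])

    def sample_area(self, fid: str) -> list[int]:
        return self.sample_areas.get(fid) or self.footprints[fid]

    def region_footprints(self, region: int) -> list[str]:
        return [f for f, r in self.footprint_region.items() if r == region]

    def to_json(self, path: str | Path) -> None:
        data = {
            "footprints": self.footprints,
            "footprint_region": self.footprint_region,
            "bundles": {k: list(v) for k, v in self.bundles.items()},
            "region_hemisphere": {str(k): v for k, v in self.region_hemisphere.items()},
            "sample_areas": self.sample_areas,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            footprints={k: list(map(int, v)) for k, v in data["footprints"].items()},
            footprint_region={k: int(v) for k, v in data["footprint_region"].items()},
            bundles={k: (v[0], v[1]) for k, v in data["bundles"].items()},
            region_hemisphere={int(k): v for k, v in data["region_hemisphere"].items()},
            sample_areas={k: list(map(int, v))
                          for k, v in data.get("sample_areas", {}).items()},
            params=data["params"],
        )


def _hop_distances(tris: set[int], sources: Sequence[int],
                   surface: LabeledSurface) -> dict[int, int]:
    dist = {s: 0 for s in sources}
    frontier = list(sources)
    while frontier:
        nxt = []
        for t in frontier:
            for nb in sorted(surface.edge_adjacency[t]):
                if nb in tris and nb not in dist:
                    dist[nb] = dist[t] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


def _farthest_point_seeds(tris: list[int], k: int, surface: LabeledSurface,
                          rng: np.random.Generator) -> list[int]:
    """k well-separated seed triangles: random first, then farthest-point."""
    tri_set = set(tris)
    seeds = [tris[int(rng.integers(len(tris)))]]
    while len(seeds) < k:
        dist = _hop_distances(tri_set, seeds, surface)
        seeds.append(max(tris, key=lambda t: (dist.get(t, -1), -t)))
    return seeds


def _bfs_partition(tris: list[int], seeds: list[int],
                   surface: LabeledSurface) -> list[list[int]]:
    """Multi-source BFS assignment of ``tris`` to the nearest seed triangle."""
    tri_set = set(tris)
    owner = {s: i for i, s in enumerate(seeds)}
    frontier = list(seeds)
    while frontier:
        nxt = []
        for t in frontier:
            for nb in sorted(surface.edge_adjacency[t]):
                if nb in tri_set and nb not in owner:
                    owner[nb] = owner[t]
                    nxt.append(nb)
        frontier = nxt
    patches: list[list[int]] = [[] for _ in seeds]
    for t, i in owner.items():
        patches[i].append(t)
    return [sorted(p) for p in patches]


def _erode(fp: set[int], surface: LabeledSurface, rings: int) -> set[int]:
    out = set(fp)
    for _ in range(rings):
        out = {t for t in out if set(surface.vertex_adjacency[t]) <= out}
    return out


def footprint_interior(fp: set[int], surface: LabeledSurface,
                       rings: int = 2) -> list[int]:
    """Deepest non-empty erosion of the footprint, up to ``rings`` rings.

    Sampling fiber endpoints two rings deep keeps the endpoint's
    vertex-neighborhood inside the footprint even when jitter drifts the
    located endpoint into an adjacent triangle.
    """
    for r in range(rings, 0, -1):
        interior = _erode(fp, surface, r)
        if interior:
            return sorted(interior)
    return sorted(fp)


def make_ground_truth(surface: LabeledSurface, seed: int,
                      footprints_per_region: tuple[int, int] = (2, 4),
                      overlap_spec: Optional[Sequence[tuple[int, float]]] = None,
                      sigma_mm: float = 0.5, flip_prob: float = 0.5,
                      distractor_frac: float = 0.2,
                      fibers_per_bundle: int = 30,
                      threshold_mm: float = 6.0) -> GroundTruth:
    """Partition each region into disjoint footprints and pair them into bundles.

    ``overlap_spec`` entries ``(region, fraction)`` add one extra footprint to
    that region sharing the given fraction of footprint 0's triangles (used to
    exercise the merge machinery).
    """
    rng = np.random.default_rng(seed)
    regions = sorted(set(int(v) for v in surface.triangle_labels))
    hemis = {r: ("left" if i < (len(regions) + 1) // 2 else "right")
             for i, r in enumerate(regions)}
    footprints: dict[str, list[int]] = {}
    footprint_region: dict[str, int] = {}
    sample_areas: dict[str, list[int]] = {}
    scaffold: dict[str, set[int]] = {}

    def _expand(core: set[int], region: int) -> list[int]:
        # expected imprint: every core triangle is hit by many endpoints and
        # each endpoint contributes its vertex-neighborhood, so the support
        # converges to the one-ring expansion clipped to the region
        out = set(core)
        for t in core:
            out.update(surface.vertex_adjacency[t])
        return sorted(t for t in out
                      if int(surface.triangle_labels[t]) == region)

    for region in regions:
        tris = [int(t) for t in surface.region_triangles(region)]
        k = int(rng.integers(footprints_per_region[0], footprints_per_region[1] + 1))
        k = max(1, min(k, len(tris) // 30))
        patches = None
        while k >= 1:
            ok = False
            for _ in range(8):
                seeds = _farthest_point_seeds(tris, k, surface, rng)
                patches = _bfs_partition(tris, seeds, surface)
                # each patch must survive a two-ring erosion so endpoint
                # neighborhoods stay strictly inside the patch
                interiors = [len(_erode(set(p), surface, 2)) for p in patches]
                if all(n >= 3 for n in interiors):
                    ok = True
                    break
            if ok:
                break
            k -= 1
        assert patches is not None
        for i, patch in enumerate(patches):
            fid = f"R{region}F{i}"
            core = set(footprint_interior(set(patch), surface, rings=2))
            footprints[fid] = _expand(core, region)
            sample_areas[fid] = sorted(core)
            footprint_region[fid] = region
            scaffold[fid] = set(patch)

    if overlap_spec:
        for region, fraction in overlap_spec:
            base_id = f"R{region}F0"
            core_a = set(sample_areas[base_id])
            fp_a = set(footprints[base_id])
            pool = set(scaffold[base_id])
            m = len(core_a)
            # search the scaffold for a same-size ball whose expanded
            # footprint overlaps the base footprint closest to `fraction`
            best: Optional[tuple[float, int, set[int]]] = None
            for seed_t in sorted(pool):
                core_b = set(_grow_patch(pool, seed_t, m, surface))
                fp_b = set(_expand(core_b, region))
                ov = len(fp_a & fp_b) / min(len(fp_a), len(fp_b))
                cand = (abs(ov - fraction), seed_t, core_b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
            assert best is not None
            fid = f"R{region}OV"
            footprints[fid] = _expand(best[2], region)
            sample_areas[fid] = sorted(best[2])
            footprint_region[fid] = region

    # pair footprints within each hemisphere; each footprint ends one bundle
    bundles: dict[str, tuple[str, str]] = {}
    pair_index: dict[tuple[str, int, int], int] = {}
    for hemi in ("left", "right"):
        fids = sorted(f for f, r in footprint_region.items() if hemis[r] == hemi)
        rng.shuffle(fids)
        if len(fids) % 2 == 1:
            fids.append(fids[0])  # odd count: first footprint anchors two bundles
        prefix = "lh" if hemi == "left" else "rh"
        for a, b in zip(fids[0::2], fids[1::2]):
            ra, rb = footprint_region[a], footprint_region[b]
            key = (prefix, ra, rb)
            idx = pair_index.get(key, 0)
            pair_index[key] = idx + 1
            name = f"{prefix}_R{ra}-R{rb}_{idx}"
            bundles[name] = (a, b)

    return GroundTruth(
        footprints=footprints, footprint_region=footprint_region,
        bundles=bundles, region_hemisphere=hemis, sample_areas=sample_areas,
        params={
            "seed": seed, "sigma_mm": sigma_mm, "flip_prob": flip_prob,
            "distractor_frac": distractor_frac,
            "fibers_per_bundle": fibers_per_bundle,
            "threshold_mm": threshold_mm,
        },
    )


def _grow_patch(within: set[int], start: int, n: int,
                surface: LabeledSurface) -> list[int]:
    """BFS-grow a connected patch of ``n`` triangles inside ``within``."""
    seen = {start}
    order = [start]
    frontier = [start]
    while frontier and len(order) < n:
        nxt = []
        for t in frontier:
            for nb in sorted(surface.edge_adjacency[t]):
                if nb in within and nb not in seen:
                    seen.add(nb)
                    order.append(nb)
                    nxt.append(nb)
                    if len(order) >= n:
                        break
            if len(order) >= n:
                break
        frontier = nxt
    return order[:n]


def _grow_from_boundary(core: Sequence[int], pool: set[int], n: int,
                        surface: LabeledSurface) -> list[int]:
    """Accrete up to ``n`` triangles from ``pool`` adjacent to ``core``."""
    out: list[int] = []
    current = set(core)
    while len(out) < n:
        ring = sorted(t for t in pool
                      if t not in current and surface.edge_adjacency[t] & current)
        if not ring:
            break
        for t in ring:
            out.append(t)
            current.add(t)
            if len(out) >= n:
                break
    return out


# ---------------------------------------------------------------------------
# atlas + subjects
# ---------------------------------------------------------------------------

def _random_point_in_triangle(tri: int, surface: LabeledSurface,
                              rng: np.random.Generator,
                              shrink: float = 0.3) -> np.ndarray:
    """Uniform point in the triangle, pulled toward the centroid.

    ``shrink`` < 1 keeps sampled endpoints away from triangle edges so that
    subject-level Gaussian jitter almost never drifts an endpoint into a
    neighboring triangle.
    """
    a, b, c = surface.vertices[surface.triangles[tri]]
    r1, r2 = rng.random(), rng.random()
    s1 = np.sqrt(r1)
    p = a * (1 - s1) + b * (s1 * (1 - r2)) + c * (s1 * r2)
    centroid = (a + b + c) / 3.0
    return centroid + shrink * (p - centroid)


def _arc_fiber(p0: np.ndarray, p1: np.ndarray, rng: np.random.Generator,
               bulge: float = 0.35) -> np.ndarray:
    """21-point arc from p0 to p1 bulging toward the sphere interior.

    Built densely then resampled so the 21 points are arc-length equidistant,
    matching how subject tractograms are resampled before segmentation.
    """
    ts = np.linspace(0.0, 1.0, 200)
    chord = np.outer(1 - ts, p0) + np.outer(ts, p1)
    depth = bulge * (0.8 + 0.4 * rng.random())
    scale = 1.0 - depth * np.sin(np.pi * ts)
    dense = chord * scale[:, None]
    return resample_streamline(dense, N_POINTS).points


def make_synthetic_atlas(surface: LabeledSurface, gt: GroundTruth, seed: int
                         ) -> BundleAtlas:
    """Bundle fibers arcing between the interiors of each footprint pair.

    Endpoints are sampled only from footprint-interior triangles so that
    endpoint neighborhoods stay inside the footprint.  Per-bundle threshold
    and fiber count come from the ground-truth parameters.
    """
    rng = np.random.default_rng(seed)
    n_fibers = int(gt.params.get("fibers_per_bundle", 30))
    threshold = float(gt.params.get("threshold_mm", 6.0))
    bundles = []
    for name in sorted(gt.bundles):
        fa, fb = gt.bundles[name]
        if not gt.footprints[fa] or not gt.footprints[fb]:
            raise ValueError(f"bundle {name} has an empty footprint")
        int_a = gt.sample_area(fa)
        int_b = gt.sample_area(fb)
        fibers = []
        for _ in range(n_fibers):
            ta = int_a[int(rng.integers(len(int_a)))]
            tb = int_b[int(rng.integers(len(int_b)))]
            p0 = _random_point_in_triangle(ta, surface, rng)
            p1 = _random_point_in_triangle(tb, surface, rng)
            fibers.append(_arc_fiber(p0, p1, rng))
        fibers_arr = np.stack(fibers)
        ra, rb = gt.footprint_region[fa], gt.footprint_region[fb]
        bundles.append(Bundle(
            name=name, fibers=list(fibers_arr), threshold_mm=threshold,
            centroid=fibers_arr.mean(axis=0),
            region_start=ra, region_end=rb,
            hemisphere=gt.region_hemisphere[ra]))
    return BundleAtlas(bundles=bundles)


def _min_distance_to_atlas(fiber: np.ndarray, stacked: np.ndarray) -> float:
    d_direct = np.linalg.norm(stacked - fiber[None], axis=2).max(axis=1)
    d_flip = np.linalg.norm(stacked - fiber[None, ::-1], axis=2).max(axis=1)
    return float(np.minimum(d_direct, d_flip).min())


def simulate_subject(atlas: BundleAtlas, gt: GroundTruth, subject_seed: int,
                     sigma_mm: Optional[float] = None,
                     flip_prob: Optional[float] = None,
                     distractor_frac: Optional[float] = None
                     ) -> tuple[Tractogram, list[str]]:
    """One subject: jittered/flipped atlas fibers plus deep distractors.

    Returns the shuffled tractogram and, per streamline, the source bundle
    name ("" for distractors).
    """
    rng = np.random.default_rng(subject_seed)
    sigma = gt.params["sigma_mm"] if sigma_mm is None else sigma_mm
    flip_p = gt.params["flip_prob"] if flip_prob is None else flip_prob
    dfrac = gt.params["distractor_frac"] if distractor_frac is None else distractor_frac
    stacked = np.stack([f for b in atlas.bundles for f in b.fibers])
    max_thr = max(b.threshold_mm for b in atlas.bundles)
    radius = float(np.linalg.norm(
        np.asarray(gt.params.get("radius_hint", [50.0, 0, 0]))))

    fibers: list[np.ndarray] = []
    sources: list[str] = []
    for b in sorted(atlas.bundles, key=lambda b: b.name):
        for f in b.fibers:
            g = f + rng.normal(scale=sigma, size=f.shape) if sigma > 0 else f.copy()
            if rng.random() < flip_p:
                g = g[::-1].copy()
            fibers.append(g)
            sources.append(b.name)
    n_distractors = int(round(dfrac * len(fibers)))
    made = 0
    while made < n_distractors:
        center = rng.normal(scale=0.08 * radius, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = (0.1 + 0.1 * rng.random()) * radius
        ts = np.linspace(-0.5, 0.5, N_POINTS)
        f = center[None] + np.outer(ts * length, direction)
        f += rng.normal(scale=max(sigma, 0.1), size=f.shape)
        if _min_distance_to_atlas(f, stacked) <= max_thr:
            continue  # rejection sampling keeps distractors unsegmentable
        fibers.append(f)
        sources.append("")
        made += 1
    order = rng.permutation(len(fibers))
    streamlines = [Streamline(points=fibers[k], id=i)
                   for i, k in enumerate(order)]
    return (Tractogram(streamlines=streamlines, space_tag="synthetic"),
            [sources[k] for k in order])


@dataclass
class Cohort:
    surface: LabeledSurface
    atlas: BundleAtlas
    gt: GroundTruth
    tractograms: list[Tractogram]
    sources: list[list[str]]          # per subject, per streamline source bundle


def make_cohort(seed: int, n_subjects: int = 10, subdivisions: int = 3,
                n_regions: int = 8,
                footprints_per_region: tuple[int, int] = (2, 4),
                overlap_spec: Optional[Sequence[tuple[int, float]]] = None,
                sigma_mm: float = 0.5, flip_prob: float = 0.5,
                distractor_frac: float = 0.2, fibers_per_bundle: int = 30,
                threshold_mm: float = 6.0) -> Cohort:
    """End-to-end cohort builder used by tests and the CLI."""
    ss = np.random.SeedSequence(seed)
    s_mesh, s_gt, s_atlas, s_subj = ss.spawn(4)
    surface = make_labeled_sphere(subdivisions, n_regions,
                                  int(s_mesh.generate_state(1)[0]))
    gt = make_ground_truth(surface, int(s_gt.generate_state(1)[0]),
                           footprints_per_region=footprints_per_region,
                           overlap_spec=overlap_spec, sigma_mm=sigma_mm,
                           flip_prob=flip_prob, distractor_frac=distractor_frac,
                           fibers_per_bundle=fibers_per_bundle,
                           threshold_mm=threshold_mm)
    atlas = make_synthetic_atlas(surface, gt, int(s_atlas.generate_state(1)[0]))
    subj_seeds = s_subj.spawn(n_subjects)
    tractograms, sources = [], []
    for sseq in subj_seeds:
        t, src = simulate_subject(atlas, gt, int(sseq.generate_state(1)[0]))
        tractograms.append(t)
        sources.append(src)
    return Cohort(surface=surface, atlas=atlas, gt=gt,
                  tractograms=tractograms, sources=sources)


# ---------------------------------------------------------------------------
# on-disk cohort layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "atlas").mkdir(parents=True, exist_ok=True)
    (out / "subjects").mkdir(exist_ok=True)
    write_labeled_surface(cohort.surface, out / "mesh.obj", out / "labels.txt")
    cohort.gt.to_json(out / "ground_truth.json")
    rows = ["name\tthreshold_mm\tregion_start\tregion_end\themisphere"]
    for b in sorted(cohort.atlas.bundles, key=lambda b: b.name):
        write_tractogram(
            Tractogram([Streamline(points=f, id=i) for i, f in enumerate(b.fibers)]),
            out / "atlas" / f"{b.name}.tck")
        rows.append(f"{b.name}\t{b.threshold_mm}\t{b.region_start}"
                    f"\t{b.region_end}\t{b.hemisphere}")
    (out / "atlas" / "bundles.tsv").write_text("\n".join(rows) + "\n")
    for i, t in enumerate(cohort.tractograms):
        write_tractogram(t, out / "subjects" / f"subject_{i:03d}.tck")


def read_atlas(atlas_dir: str | Path) -> BundleAtlas:
    atlas_dir = Path(atlas_dir)
    bundles = []
    lines = (atlas_dir / "bundles.tsv").read_text().strip().splitlines()
    for line in lines[1:]:
        name, thr, rs, re_, hemi = line.split("\t")
        t = read_tractogram(atlas_dir / f"{name}.tck")
        fibers = np.stack([s.points for s in t.streamlines])
        bundles.append(Bundle(
            name=name, fibers=list(fibers), threshold_mm=float(thr),
            centroid=fibers.mean(axis=0), region_start=int(rs),
            region_end=int(re_), hemisphere=hemi))
    return BundleAtlas(bundles=bundles)


def read_cohort(cohort_dir: str | Path) -> Cohort:
    cohort_dir = Path(cohort_dir)
    surface = read_labeled_surface(cohort_dir / "mesh.obj", cohort_dir / "labels.txt")
    gt = GroundTruth.from_json(cohort_dir / "ground_truth.json")
    atlas = read_atlas(cohort_dir / "atlas")
    tractograms = [read_tractogram(p)
                   for p in sorted((cohort_dir / "subjects").glob("subject_*.tck"))]
    return Cohort(surface=surface, atlas=atlas, gt=gt,
                  tractograms=tractograms, sources=[[] for _ in tractograms])
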