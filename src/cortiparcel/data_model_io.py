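"""Core domain types, streamline/surface IO, mesh adjacency and resampling.

Coordinates are millimetres throughout.  Surfaces and tractograms are assumed
to live in the same (co-registered) space; no transform machinery is provided.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import nibabel as nib


class TractogramFormatError(ValueError):
    """Raised when a streamline file cannot be parsed or violates invariants."""


class LabelMismatchError(ValueError):
    """Raised when a label array does not match the mesh vertex count."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Streamline:
    """An ordered 3D polyline (one fiber)."""

    points: np.ndarray  # (n, 3) float64
    id: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"streamline points must be (n, 3), got {self.points.shape}")
        if len(self.points) < 2:
            raise ValueError("streamline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("streamline contains non-finite coordinates")


@dataclass
class Tractogram:
    """A collection of streamlines with contiguous ids starting at 0."""

    streamlines: list[Streamline]
    space_tag: str = "subject"

    def __post_init__(self) -> None:
        for i, s in enumerate(self.streamlines):
            if s.id != i:
                raise ValueError(f"streamline ids must be contiguous from 0 (got {s.id} at {i})")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class Bundle:
    """A named atlas bundle of corresponding-point-resampled fibers.

    ``name`` follows the short-association convention ``lh_PoC-PrC_0``
    (hemisphere prefix, the two connected region codes, index).  Long-range
    bundles with opaque names carry their region pair explicitly in
    ``region_start`` / ``region_end``.
    """

    name: str
    fibers: list[np.ndarray]          # each (21, 3)
    threshold_mm: float
    centroid: np.ndarray              # (21, 3)
    region_start: int
    region_end: int
    hemisphere: str                   # "left" | "right"

    def __post_init__(self) -> None:
        self.fibers = [np.asarray(f, dtype=np.float64) for f in self.fibers]
        for f in self.fibers:
            if f.shape != (21, 3):
                raise ValueError(f"bundle {self.name}: fibers must have 21 points")
        self.centroid = np.asarray(self.centroid, dtype=np.float64)
        if self.centroid.shape != (21, 3):
            raise ValueError(f"bundle {self.name}: centroid must have 21 points")
        if self.threshold_mm <= 0:
            raise ValueError(f"bundle {self.name}: threshold_mm must be positive")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"bundle {self.name}: bad hemisphere {self.hemisphere!r}")


@dataclass
class BundleAtlas:
    bundles: list[Bundle]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bundles]
        if len(set(names)) != len(names):
            raise ValueError("bundle names must be unique")

    def __len__(self) -> int:
        return len(self.bundles)

    def by_name(self, name: str) -> Bundle:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)


def derive_triangle_label(tri: Sequence[int], vertex_labels: np.ndarray) -> int:
    """Label of a triangle from its three vertex labels.

    Majority wins; if all three labels differ, the label of the
    lowest-index vertex is used.
    """
    i, j, k = tri
    li, lj, lk = int(vertex_labels[i]), int(vertex_labels[j]), int(vertex_labels[k])
    if li == lj or li == lk:
        return li
    if lj == lk:
        return lj
    # all distinct: lowest vertex index decides
    order = sorted([(i, li), (j, lj), (k, lk)])
    return order[0][1]


@dataclass
class LabeledSurface:
    """Shared-topology triangle mesh with per-vertex anatomical labels.

    ``vertex_adjacency[t]`` holds triangles sharing at least one vertex with
    triangle ``t`` (self excluded); ``edge_adjacency[t]`` holds triangles
    sharing a full edge (at most 3 on a closed manifold).
    """

    vertices: np.ndarray              # (nv, 3) float64
    triangles: np.ndarray             # (nt, 3) int
    vertex_labels: np.ndarray         # (nv,) int
    triangle_labels: np.ndarray = field(init=False)
    vertex_adjacency: list[frozenset] = field(init=False)
    edge_adjacency: list[frozenset] = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)
        nv = len(self.vertices)
        if len(self.vertex_labels) != nv:
            raise LabelMismatchError(
                f"{len(self.vertex_labels)} labels for {nv} vertices")
        if self.triangles.size and self.triangles.max() >= nv:
            raise ValueError("triangle index out of vertex range")
        self.triangle_labels = np.array(
            [derive_triangle_label(t, self.vertex_labels) for t in self.triangles],
            dtype=np.int64,
        )
        self._build_adjacency()

    def _build_adjacency(self) -> None:
        nt = len(self.triangles)
        vert_to_tris: dict[int, list[int]] = {}
        for t, tri in enumerate(self.triangles):
            for v in tri:
                vert_to_tris.setdefault(int(v), []).append(t)
        vertex_adj: list[set] = [set() for _ in range(nt)]
        for tris in vert_to_tris.values():
            for t in tris:
                vertex_adj[t].update(tris)
        edge_to_tris: dict[tuple[int, int], list[int]] = {}
        for t, tri in enumerate(self.triangles):
            a, b, c = (int(x) for x in tri)
            for e in ((a, b), (b, c), (a, c)):
                key = (min(e), max(e))
                edge_to_tris.setdefault(key, []).append(t)
        edge_adj: list[set] = [set() for _ in range(nt)]
        for tris in edge_to_tris.values():
            for t in tris:
                edge_adj[t].update(tris)
        self.vertex_adjacency = [frozenset(s - {t}) for t, s in enumerate(vertex_adj)]
        self.edge_adjacency = [frozenset(s - {t}) for t, s in enumerate(edge_adj)]

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def region_triangles(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.triangle_labels == region)


@dataclass
class PipelineConfig:
    """Thresholds and geometry tolerances shared by all pipeline stages."""

    size_thr: float = 0.10
    dc_thr: float = 0.15
    idc_thr: float = 0.10
    rng_seed: int = 0
    ray_extension_mm: float = 2.0     # how far beyond the endpoint a ray hit may land
    endpoint_radius_mm: float = 3.0   # candidate-triangle search radius around an endpoint
    size_rule: str = "mean_subparcel"  # or "region_fraction"

    def __post_init__(self) -> None:
        for attr in ("size_thr", "dc_thr", "idc_thr"):
            v = getattr(self, attr)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{attr} must lie in (0, 1), got {v}")
        if self.size_rule not in ("mean_subparcel", "region_fraction"):
            raise ValueError(f"unknown size_rule {self.size_rule!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        section = data.get("cortiparcel", data)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in section.items() if k in known})

    def to_toml(self, path: str | Path) -> None:
        lines = ["[cortiparcel]"]
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# streamline IO (TRK/TCK via nibabel)
# ---------------------------------------------------------------------------

def read_tractogram(path: str | Path, space_tag: str = "subject") -> Tractogram:
    path = Path(path)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises HeaderError/ValueError/OSError dialects
        raise TractogramFormatError(f"cannot read {path.name}: {exc}") from exc
    streamlines = []
    for i, pts in enumerate(tf.streamlines):
        pts = np.asarray(pts, dtype=np.float64)
        if len(pts) < 2 or not np.all(np.isfinite(pts)):
            raise TractogramFormatError(
                f"{path.name}: streamline {i} is degenerate (needs >=2 finite points)")
        streamlines.append(Streamline(points=pts, id=i))
    return Tractogram(streamlines=streamlines, space_tag=space_tag)


def write_tractogram(t: Tractogram, path: str | Path) -> None:
    path = Path(path)
    nt = nib.streamlines.Tractogram(
        [s.points for s in t.streamlines], affine_to_rasmm=np.eye(4))
    nib.streamlines.save(nt, str(path))


# ---------------------------------------------------------------------------
# surface IO (GIfTI or OBJ + text labels)
# ---------------------------------------------------------------------------

def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            vertices.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            if len(idx) != 3:
                raise ValueError(f"{path.name}: only triangle faces supported")
            faces.append(idx)
    return np.asarray(vertices, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def _write_obj(vertices: np.ndarray, triangles: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        for v in vertices:
            fh.write(f"v {v[0]:.8f} {v[1]:.8f} {v[2]:.8f}\n")
        for t in triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def read_labeled_surface(mesh_path: str | Path, labels_path: str | Path) -> LabeledSurface:
    mesh_path, labels_path = Path(mesh_path), Path(labels_path)
    if mesh_path.suffix == ".gii":
        img = nib.load(str(mesh_path))
        vertices = np.asarray(img.agg_data("pointset"), dtype=np.float64)
        triangles = np.asarray(img.agg_data("triangle"), dtype=np.int64)
    elif mesh_path.suffix == ".obj":
        vertices, triangles = _read_obj(mesh_path)
    else:
        raise ValueError(f"unsupported mesh format: {mesh_path.suffix}")
    if labels_path.suffix == ".gii":
        labels = np.asarray(nib.load(str(labels_path)).agg_data(), dtype=np.int64).ravel()
    else:
        labels = np.loadtxt(labels_path, dtype=np.int64).ravel()
    return LabeledSurface(vertices=vertices, triangles=triangles, vertex_labels=labels)


def write_labeled_surface(surface: LabeledSurface, mesh_path: str | Path,
                          labels_path: str | Path) -> None:
    mesh_path, labels_path = Path(mesh_path), Path(labels_path)
    if mesh_path.suffix == ".gii":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(surface.vertices.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(surface.triangles.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, str(mesh_path))
    elif mesh_path.suffix == ".obj":
        _write_obj(surface.vertices, surface.triangles, mesh_path)
    else:
        raise ValueError(f"unsupported mesh format: {mesh_path.suffix}")
    np.savetxt(labels_path, surface.vertex_labels, fmt="%d")


def write_label_array(labels: np.ndarray, path: str | Path) -> None:
    """Write a per-element integer label array (text, or .gii label array)."""
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(np.asarray(labels, dtype=np.int32),
                                     intent="NIFTI_INTENT_LABEL")])
        nib.save(img, str(path))
    else:
        np.savetxt(path, np.asarray(labels, dtype=np.int64), fmt="%d")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_streamline(s: Streamline | np.ndarray, n: int) -> Streamline:
    """Resample a polyline to ``n`` points equidistant in arc length.

    First and last points are preserved exactly.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    pts = s.points if isinstance(s, Streamline) else np.asarray(s, dtype=np.float64)
    fid = s.id if isinstance(s, Streamline) else 0
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seglen.sum())
    if total <= 0.0:
        raise ValueError("cannot resample a zero-length fiber")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(targets, cum, pts[:, d]) for d in range(3)])
    out[0], out[-1] = pts[0], pts[-1]
    return Streamline(points=out, id=fid)


def resample_tractogram(t: Tractogram, n: int = 21) -> Tractogram:
    return Tractogram(
        streamlines=[resample_streamline(s, n) for s in t.streamlines],
        space_tag=t.space_tag,
    )
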