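"""Reproducibility and similarity analysis of parcellations.

Binary connectivity matrices from whole tractograms, Dice reproducibility
across subject pairs, parcel-by-parcel similarity with best-match binning,
coefficient of variation, and volumetric-label-to-mesh mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cortex_parcellation import HardParcellation, UNLABELED
from .data_model_io import LabeledSurface, PipelineConfig, Tractogram
from .mesh_intersection import TriangleGrid, locate_endpoint

log = logging.getLogger(__name__)

DICE_BINS = ((0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9))


def build_connectivity_matrix(t: Tractogram, parc: HardParcellation,
                              surface: LabeledSurface, cfg: PipelineConfig,
                              grid: Optional[TriangleGrid] = None) -> np.ndarray:
    """n x n binary symmetric matrix over final sub-parcels.

    Every fiber of the whole tractogram is intersected with the mesh; fibers
    with unresolved or unlabeled ends are ignored.  The diagonal (intra-parcel
    connections) is permitted.
    """
    n = len(parc.label_table)
    if n == 0:
        raise ValueError("parcellation has no labels")
    if max(parc.label_table) >= n:
        raise ValueError("label table is not dense; relabel first")
    if grid is None:
        grid = TriangleGrid(surface)
    m = np.zeros((n, n), dtype=np.int8)
    for s in t.streamlines:
        ta = locate_endpoint(s.points, "first", surface, cfg, grid)
        tb = locate_endpoint(s.points, "last", surface, cfg, grid)
        if ta is None or tb is None:
            continue
        a, b = int(parc.labels[ta]), int(parc.labels[tb])
        if a == UNLABELED or b == UNLABELED:
            continue
        m[a, b] = 1
        m[b, a] = 1
    return m


def dice_sets(a: set, b: set) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); both-empty is defined as 0."""
    if not a and not b:
        log.warning("dice_sets: both sets empty, returning 0")
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def _matrix_cells(m: np.ndarray) -> set[tuple[int, int]]:
    # upper triangle incl. diagonal; symmetry would double-count otherwise
    r, c = np.nonzero(np.triu(m))
    return set(zip(r.tolist(), c.tolist()))


def pairwise_matrix_dice(matrices: Sequence[np.ndarray]
                         ) -> tuple[float, list[tuple[int, int, float]]]:
    """Mean Dice over all unordered subject pairs of connectivity matrices."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 subjects")
    shape = matrices[0].shape
    for m in matrices:
        if m.shape != shape:
            raise ValueError("connectivity matrix shape mismatch")
    cells = [_matrix_cells(m) for m in matrices]
    table = [(i, j, dice_sets(cells[i], cells[j]))
             for i, j in combinations(range(len(matrices)), 2)]
    mean = float(np.mean([d for _, _, d in table]))
    return mean, table


@dataclass
class SimilarityReport:
    pairwise: dict[tuple[int, int], float]          # (label_a, label_b) -> dice
    best_a: dict[int, tuple[int, float]]            # a-parcel -> (b-parcel, dice)
    best_b: dict[int, tuple[int, float]]
    score: float                                    # symmetrized mean best-match dice
    bin_counts: dict[tuple[float, float], int] = field(default_factory=dict)


def _parcel_sets(labels: np.ndarray) -> dict[int, set[int]]:
    out: dict[int, set[int]] = {}
    for t, v in enumerate(labels):
        v = int(v)
        if v != UNLABELED:
            out.setdefault(v, set()).add(t)
    return out


def compare_parcellations(labels_a: np.ndarray, labels_b: np.ndarray
                          ) -> SimilarityReport:
    """Triangle-set Dice for every parcel pair plus best matches and bins.

    The atlas-pair score is symmetrized as the mean of the two directional
    best-match means; bin counts are over A's best-match values.
    """
    sets_a = _parcel_sets(labels_a)
    sets_b = _parcel_sets(labels_b)
    pairwise: dict[tuple[int, int], float] = {}
    for la, sa in sets_a.items():
        for lb, sb in sets_b.items():
            pairwise[(la, lb)] = dice_sets(sa, sb)
    best_a = {}
    for la in sets_a:
        lb, d = max(((lb, pairwise[(la, lb)]) for lb in sets_b),
                    key=lambda e: (e[1], -e[0]))
        best_a[la] = (lb, d)
    best_b = {}
    for lb in sets_b:
        la, d = max(((la, pairwise[(la, lb)]) for la in sets_a),
                    key=lambda e: (e[1], -e[0]))
        best_b[lb] = (la, d)
    mean_a = float(np.mean([d for _, d in best_a.values()])) if best_a else 0.0
    mean_b = float(np.mean([d for _, d in best_b.values()])) if best_b else 0.0
    bins = {rng: sum(1 for _, d in best_a.values() if rng[0] <= d < rng[1])
            for rng in DICE_BINS}
    return SimilarityReport(pairwise=pairwise, best_a=best_a, best_b=best_b,
                            score=(mean_a + mean_b) / 2.0, bin_counts=bins)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Population standard deviation divided by the mean."""
    arr = np.asarray(values, dtype=np.float64)
    mean = float(arr.mean())
    if mean <= 0.0:
        raise ValueError("coefficient of variation requires a positive mean")
    return float(arr.std(ddof=0)) / mean


def map_volume_labels_to_mesh(volume: np.ndarray, affine: np.ndarray,
                              surface: LabeledSurface) -> np.ndarray:
    """Per-vertex labels from the nearest labeled (non-zero) voxel center.

    Ties at equal distance resolve to the lowest voxel linear index.
    """
    volume = np.asarray(volume)
    idx = np.argwhere(volume != 0)
    if len(idx) == 0:
        raise ValueError("volume contains no labeled voxels")
    linear = np.ravel_multi_index(idx.T, volume.shape)
    order = np.argsort(linear)
    idx, linear = idx[order], linear[order]
    homog = np.column_stack([idx, np.ones(len(idx))])
    centers = (affine @ homog.T).T[:, :3]
    labels_at = volume[tuple(idx.T)]
    tree = cKDTree(centers)
    d0, _ = tree.query(surface.vertices)
    out = np.empty(len(surface.vertices), dtype=np.int64)
    for i, (v, d) in enumerate(zip(surface.vertices, d0)):
        near = tree.query_ball_point(v, d + 1e-9)
        best = min(near, key=lambda k: linear[k])  # rows sorted by linear index
        out[i] = int(labels_at[best])
    return out
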