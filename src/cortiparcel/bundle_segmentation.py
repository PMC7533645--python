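"""Classify tractogram fibers against a bundle atlas (Step 1).

A fiber is compared to every atlas fiber by the maximum Euclidean distance
between corresponding points, evaluated in both orientations.  It is assigned
to the closest bundle whose per-bundle distance threshold it satisfies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model_io import BundleAtlas, Tractogram


@dataclass
class SegmentedFiber:
    fiber_id: int
    bundle_name: str
    distance_mm: float
    flipped: bool


def fiber_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Max corresponding-point distance over direct and reversed orientations.

    Returns ``(distance, flipped)`` where ``flipped`` is True iff the reversed
    orientation strictly wins; ties favor the direct orientation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"point-count mismatch: {a.shape} vs {b.shape}")
    d_direct = float(np.linalg.norm(a - b, axis=1).max())
    d_flip = float(np.linalg.norm(a - b[::-1], axis=1).max())
    if d_flip < d_direct:
        return d_flip, True
    return d_direct, False


class _AtlasStack:
    """Atlas fibers stacked for vectorized distance evaluation.

    Bundles are laid out contiguously in ascending-name order so per-bundle
    minima can be computed with ``reduceat`` and name-ascending tie-breaks
    fall out of the ordering.
    """

    def __init__(self, atlas: BundleAtlas):
        if not atlas.bundles:
            raise ValueError("empty atlas")
        self.bundles = sorted(atlas.bundles, key=lambda b: b.name)
        self.names = [b.name for b in self.bundles]
        self.fibers = np.stack(
            [f for b in self.bundles for f in b.fibers])  # (Na, 21, 3)
        counts = [len(b.fibers) for b in self.bundles]
        self.offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
        self.thresholds = np.array([b.threshold_mm for b in self.bundles])


def segment_tractogram(t: Tractogram, atlas: BundleAtlas,
                       chunk_size: int = 256) -> list[SegmentedFiber]:
    """Assign each fiber to its closest atlas bundle within threshold.

    Fibers failing every bundle's threshold are omitted.  Ties between
    bundles at equal distance break by bundle name ascending; ties between
    atlas fibers break by atlas-fiber index; orientation ties favor direct.
    """
    stack = _AtlasStack(atlas)
    npts = stack.fibers.shape[1]
    pts = []
    for s in t.streamlines:
        if s.points.shape != (npts, 3):
            raise ValueError(
                f"fiber {s.id} has {len(s.points)} points; expected {npts} "
                "(resample the tractogram first)")
        pts.append(s.points)
    if not pts:
        return []
    subject = np.stack(pts)  # (F, 21, 3)
    out: list[SegmentedFiber] = []
    atlas_flipped_view = stack.fibers[:, ::-1, :]
    for lo in range(0, len(subject), chunk_size):
        block = subject[lo:lo + chunk_size]
        diff = block[:, None, :, :] - stack.fibers[None, :, :, :]
        d_direct = np.sqrt((diff ** 2).sum(-1)).max(-1)
        diff = block[:, None, :, :] - atlas_flipped_view[None, :, :, :]
        d_flip = np.sqrt((diff ** 2).sum(-1)).max(-1)
        dist = np.minimum(d_direct, d_flip)          # (n, Na)
        per_bundle = np.minimum.reduceat(dist, stack.offsets, axis=1)  # (n, nb)
        eligible = per_bundle <= stack.thresholds[None, :]
        masked = np.where(eligible, per_bundle, np.inf)
        best_bundle = masked.argmin(axis=1)          # first (name-asc) on ties
        for i in range(len(block)):
            bi = int(best_bundle[i])
            if not np.isfinite(masked[i, bi]):
                continue
            start = int(stack.offsets[bi])
            stop = int(stack.offsets[bi + 1]) if bi + 1 < len(stack.offsets) \
                else stack.fibers.shape[0]
            j = start + int(dist[i, start:stop].argmin())
            flipped = bool(d_flip[i, j] < d_direct[i, j])
            out.append(SegmentedFiber(
                fiber_id=lo + i,
                bundle_name=stack.names[bi],
                distance_mm=float(dist[i, j]),
                flipped=flipped,
            ))
    return out
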