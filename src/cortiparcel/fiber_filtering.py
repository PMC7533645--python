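"""Anatomical filtering and orientation alignment of intersected fibers (Step 4).

Fibers whose end-triangle labels contradict their bundle's region pair are
removed; survivors are flipped where needed so their point order matches the
atlas centroid orientation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .bundle_segmentation import fiber_distance
from .data_model_io import Bundle, LabeledSurface
from .mesh_intersection import IntersectionRecord

log = logging.getLogger(__name__)

_SWM_NAME = re.compile(r"^(lh|rh)_([A-Za-z0-9]+)-([A-Za-z0-9]+)_(\d+)$")


@dataclass
class OrientedRecord:
    fiber_id: int
    bundle_name: str
    tri_start: int
    tri_end: int
    flipped: bool = False


@dataclass
class FilteredBundle:
    bundle_name: str
    records: list[OrientedRecord]


def parse_bundle_name(name: str,
                      metadata: Optional[Mapping[str, tuple[str, str]]] = None
                      ) -> tuple[str, str, str, int]:
    """Parse a bundle name into (hemisphere, region_start, region_end, index).

    Short-association names encode everything (``lh_PoC-PrC_0``); long-range
    names (``AR_LEFT``) resolve their region pair through ``metadata``.
    """
    m = _SWM_NAME.match(name)
    if m:
        hemi = "left" if m.group(1) == "lh" else "right"
        return hemi, m.group(2), m.group(3), int(m.group(4))
    if metadata is not None and name in metadata:
        start, end = metadata[name]
        if name.endswith("_LEFT"):
            hemi = "left"
        elif name.endswith("_RIGHT"):
            hemi = "right"
        else:
            raise ValueError(f"cannot infer hemisphere from bundle name {name!r}")
        return hemi, start, end, 0
    raise ValueError(f"unparseable bundle name {name!r} with no metadata annotation")


def filter_misclassified(bundle: Bundle,
                         records: Sequence[IntersectionRecord | OrientedRecord],
                         surface: LabeledSurface) -> FilteredBundle:
    """Keep records whose unordered end-label pair equals the bundle's region pair.

    Intra-region bundles require both ends inside their single region.
    """
    want = {bundle.region_start, bundle.region_end}
    kept: list[OrientedRecord] = []
    removed = 0
    for rec in records:
        got = {int(surface.triangle_labels[rec.tri_start]),
               int(surface.triangle_labels[rec.tri_end])}
        if got == want:
            kept.append(OrientedRecord(
                fiber_id=rec.fiber_id, bundle_name=rec.bundle_name,
                tri_start=rec.tri_start, tri_end=rec.tri_end,
                flipped=getattr(rec, "flipped", False)))
        else:
            removed += 1
    if removed:
        log.info("filter_misclassified(%s): removed %d of %d records",
                 bundle.name, removed, len(records))
    return FilteredBundle(bundle_name=bundle.name, records=kept)


def align_fiber(fiber: np.ndarray, record: OrientedRecord, bundle: Bundle
                ) -> tuple[np.ndarray, OrientedRecord]:
    """Flip a fiber (and its end-triangle pair) to match the centroid orientation."""
    pts = np.asarray(fiber, dtype=np.float64)
    _, flipped = fiber_distance(pts, bundle.centroid)
    if not flipped:
        return pts, record
    return pts[::-1].copy(), OrientedRecord(
        fiber_id=record.fiber_id, bundle_name=record.bundle_name,
        tri_start=record.tri_end, tri_end=record.tri_start, flipped=True)


def filter_bundle(bundle: Bundle, records: Sequence[IntersectionRecord],
                  fibers: Mapping[int, np.ndarray], surface: LabeledSurface
                  ) -> FilteredBundle:
    """Full Step 4 for one bundle: misclassification filter, then alignment."""
    filtered = filter_misclassified(bundle, records, surface)
    aligned = []
    for rec in filtered.records:
        _, rec2 = align_fiber(fibers[rec.fiber_id], rec, bundle)
        aligned.append(rec2)
    return FilteredBundle(bundle_name=bundle.name, records=aligned)
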