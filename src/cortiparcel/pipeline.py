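"""End-to-end orchestration of the parcellation stages with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .bundle_segmentation import SegmentedFiber, segment_tractogram
from .cortex_parcellation import ParcellationResult, parcellate
from .data_model_io import (
    BundleAtlas,
    LabeledSurface,
    PipelineConfig,
    Tractogram,
    resample_tractogram,
)
from .evaluation import build_connectivity_matrix, pairwise_matrix_dice
from .fiber_filtering import FilteredBundle, filter_bundle
from .mesh_intersection import IntersectionRecord, TriangleGrid, intersect_tractogram
from .parcel_postprocessing import postprocess, surviving_labels

log = logging.getLogger(__name__)


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    counts: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)

    def check(self) -> None:
        c = self.counts
        per = zip(c["segmented_per_subject"], c["intersected_per_subject"],
                  c["filtered_per_subject"])
        for seg, inter, filt in per:
            if not (filt <= inter <= seg):
                raise AssertionError("stage counts do not reconcile")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "counts": self.counts, "hashes": self.hashes},
            indent=1))


@dataclass
class PipelineOutput:
    result: ParcellationResult
    post_labels: np.ndarray
    manifest: RunManifest
    filtered_per_subject: list[list[FilteredBundle]]
    connectivity_dice: Optional[float] = None


def run_stages_1_to_4(tractograms: Sequence[Tractogram], surface: LabeledSurface,
                      atlas: BundleAtlas, cfg: PipelineConfig
                      ) -> tuple[list[list[FilteredBundle]], dict]:
    """Segmentation, intersection and filtering for every subject."""
    grid = TriangleGrid(surface)
    filtered_per_subject: list[list[FilteredBundle]] = []
    counts = {"fibers_per_subject": [], "segmented_per_subject": [],
              "intersected_per_subject": [], "filtered_per_subject": []}
    bundles_by_name = {b.name: b for b in atlas.bundles}
    for t in tractograms:
        t21 = resample_tractogram(t, 21)
        segmented = segment_tractogram(t21, atlas)
        records = intersect_tractogram(t21, segmented, surface, cfg, grid)
        by_bundle: dict[str, list[IntersectionRecord]] = {}
        for rec in records:
            by_bundle.setdefault(rec.bundle_name, []).append(rec)
        fibers = {s.id: s.points for s in t21.streamlines}
        subject_filtered = [
            filter_bundle(bundles_by_name[name], recs, fibers, surface)
            for name, recs in sorted(by_bundle.items())
        ]
        filtered_per_subject.append(subject_filtered)
        counts["fibers_per_subject"].append(len(t))
        counts["segmented_per_subject"].append(len(segmented))
        counts["intersected_per_subject"].append(len(records))
        counts["filtered_per_subject"].append(
            sum(len(fb.records) for fb in subject_filtered))
    return filtered_per_subject, counts


def parcellate_and_post(filtered_per_subject: Sequence[Sequence[FilteredBundle]],
                        surface: LabeledSurface, atlas: BundleAtlas,
                        cfg: PipelineConfig) -> tuple[ParcellationResult, np.ndarray]:
    """Steps 5 and 6 only — reusable for threshold sweeps on fixed stage-4 output."""
    result = parcellate(filtered_per_subject, surface, atlas, cfg)
    post = postprocess(result.hard.labels, result.pmap, surface)
    return result, post


def run_pipeline(tractograms: Sequence[Tractogram], surface: LabeledSurface,
                 atlas: BundleAtlas, cfg: PipelineConfig,
                 evaluate: bool = False) -> PipelineOutput:
    """Execute segment -> intersect -> filter -> parcellate -> postprocess.

    With ``evaluate=True``, per-subject binary connectivity matrices are built
    from the whole tractograms and their mean pairwise Dice is reported.
    """
    filtered_per_subject, counts = run_stages_1_to_4(
        tractograms, surface, atlas, cfg)
    result, post = parcellate_and_post(filtered_per_subject, surface, atlas, cfg)
    counts.update({
        "n_preliminary_subparcels": result.provenance["n_preliminary"],
        "n_after_size_filter": result.provenance["n_after_size_filter"],
        "n_merges": result.provenance["n_merges"],
        "n_final_subparcels": result.provenance["n_final"],
        "n_surviving_subparcels": len(surviving_labels(post)),
    })
    manifest = RunManifest(
        config=asdict(cfg),
        counts=counts,
        hashes={
            "surface_vertices": _sha(surface.vertices),
            "hard_labels": _sha(result.hard.labels),
            "post_labels": _sha(post),
        },
    )
    manifest.check()
    dice = None
    if evaluate and len(tractograms) >= 2:
        grid = TriangleGrid(surface)
        mats = [build_connectivity_matrix(t, result.hard, surface, cfg, grid)
                for t in tractograms]
        dice, _ = pairwise_matrix_dice(mats)
        manifest.counts["mean_connectivity_dice"] = dice
    return PipelineOutput(result=result, post_labels=post, manifest=manifest,
                          filtered_per_subject=filtered_per_subject,
                          connectivity_dice=dice)
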