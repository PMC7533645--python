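"""Morphological cleanup of the hard parcellation (Step 6).

Small edge-connected components are reassigned to their second most probable
label (or unlabeled), then one synchronous opening (erosion + dilation) is
applied, followed by a final component sweep so that every surviving
sub-parcel is a single edge-connected component.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .cortex_parcellation import ProbabilityMap, UNLABELED
from .data_model_io import LabeledSurface

log = logging.getLogger(__name__)


def connected_components(labels: np.ndarray, label: int,
                         surface: LabeledSurface) -> list[list[int]]:
    """Edge-connected components of one label, size desc then smallest-index."""
    member = np.flatnonzero(labels == label)
    member_set = set(int(t) for t in member)
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in member:
        start = int(start)
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        comp = []
        while stack:
            t = stack.pop()
            comp.append(t)
            for nb in surface.edge_adjacency[t]:
                if nb in member_set and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def remove_small_components(labels: np.ndarray, pmap: ProbabilityMap,
                            surface: LabeledSurface) -> np.ndarray:
    """Keep each label's largest component; revisit satellite triangles.

    A satellite triangle takes its second most probable label when that label
    is present among its edge-neighbors' current labels, otherwise it becomes
    unlabeled.  Labels are processed in ascending order.
    """
    out = labels.copy()
    for label in sorted(set(int(v) for v in out if v != UNLABELED)):
        comps = connected_components(out, label, surface)
        for comp in comps[1:]:
            for tri in comp:
                entries = pmap.get(tri, [])
                second = entries[1][0] if len(entries) > 1 else None
                neighbor_labels = {int(out[nb]) for nb in surface.edge_adjacency[tri]}
                if second is not None and second in neighbor_labels:
                    out[tri] = second
                else:
                    out[tri] = UNLABELED
    return out


def opening(labels: np.ndarray, surface: LabeledSurface) -> np.ndarray:
    """One synchronous erosion pass followed by one synchronous dilation pass."""
    eroded = labels.copy()
    for t in range(len(labels)):
        lab = int(labels[t])
        if lab == UNLABELED:
            continue
        for nb in surface.edge_adjacency[t]:
            if int(labels[nb]) != lab:
                eroded[t] = UNLABELED
                break
    dilated = eroded.copy()
    for t in range(len(eroded)):
        if int(eroded[t]) != UNLABELED:
            continue
        votes: dict[int, int] = {}
        for nb in surface.edge_adjacency[t]:
            lab = int(eroded[nb])
            if lab != UNLABELED:
                votes[lab] = votes.get(lab, 0) + 1
        if votes:
            dilated[t] = min(votes, key=lambda lab: (-votes[lab], lab))
    return dilated


def postprocess(labels: np.ndarray, pmap: ProbabilityMap,
                surface: LabeledSurface) -> np.ndarray:
    """Component removal, opening, and a final component sweep.

    The final sweep restores the single-component guarantee that the opening
    can break (e.g. by eroding a thin neck between two blobs).
    """
    step1 = remove_small_components(labels, pmap, surface)
    step2 = opening(step1, surface)
    step3 = remove_small_components(step2, pmap, surface)
    log.info("postprocess: labeled triangles %d -> %d",
             int((labels != UNLABELED).sum()), int((step3 != UNLABELED).sum()))
    return step3


def surviving_labels(labels: np.ndarray) -> list[int]:
    return sorted(set(int(v) for v in labels if v != UNLABELED))
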