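"""Build, filter and merge connectivity-defined sub-parcels (Step 5).

Each atlas bundle seeds two preliminary sub-parcels (one per extremity).
Fiber end-triangles accumulate counts over their vertex-neighborhood across
all subjects, clipped at anatomical-region boundaries.  Probability maps are
normalized per triangle; small sub-parcels are removed; density centers are
thresholded; overlapping candidates merge by maximal cliques of the overlap
graph; the most probable label per triangle gives the hard parcellation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx

import numpy as np

from .data_model_io import BundleAtlas, LabeledSurface, PipelineConfig
from .fiber_filtering import FilteredBundle

log = logging.getLogger(__name__)

# pmap: triangle -> [(subparcel label, probability)] sorted by (-p, label)
ProbabilityMap = dict[int, list[tuple[int, float]]]

UNLABELED = -1


@dataclass
class Subparcel:
    label: int
    name: str
    region: int
    support: dict[int, int] = field(default_factory=dict)  # triangle -> count

    @property
    def size(self) -> int:
        return len(self.support)

    @property
    def triangles(self) -> set[int]:
        return set(self.support)


@dataclass
class HardParcellation:
    labels: np.ndarray                 # (nt,) int, UNLABELED where no counts
    label_table: dict[int, str]        # label -> sub-parcel name
    regions: dict[int, int]            # label -> anatomical region code


def build_preliminary_subparcels(
        filtered_per_subject: Sequence[Sequence[FilteredBundle]],
        surface: LabeledSurface, atlas: BundleAtlas) -> list[Subparcel]:
    """Two sub-parcels per bundle, counts summed over subjects.

    Each fiber adds one count to its end triangle and every triangle of that
    triangle's vertex-neighborhood; contributions landing in a different
    anatomical region than the sub-parcel's own are discarded so sub-parcels
    respect the coarse parcellation.
    """
    bundles = sorted(atlas.bundles, key=lambda b: b.name)
    subparcels: list[Subparcel] = []
    index: dict[tuple[str, str], Subparcel] = {}
    next_label = 0
    for b in bundles:
        for end, region in (("start", b.region_start), ("end", b.region_end)):
            sp = Subparcel(label=next_label, name=f"{b.name}.{end}", region=region)
            index[(b.name, end)] = sp
            subparcels.append(sp)
            next_label += 1
    labels = surface.triangle_labels
    for subject in filtered_per_subject:
        for fb in subject:
            sp_start = index.get((fb.bundle_name, "start"))
            sp_end = index.get((fb.bundle_name, "end"))
            if sp_start is None or sp_end is None:
                raise KeyError(f"bundle {fb.bundle_name} not in atlas")
            for rec in fb.records:
                for sp, tri in ((sp_start, rec.tri_start), (sp_end, rec.tri_end)):
                    for t2 in {tri} | set(surface.vertex_adjacency[tri]):
                        if int(labels[t2]) == sp.region:
                            sp.support[t2] = sp.support.get(t2, 0) + 1
    # sub-parcels never observed carry no support and are dropped
    return [sp for sp in subparcels if sp.support]


def compute_probability_maps(subparcels: Sequence[Subparcel]) -> ProbabilityMap:
    """Per-triangle normalized label probabilities, sorted desc (ties: label asc)."""
    counts: dict[int, dict[int, int]] = {}
    for sp in subparcels:
        for tri, n in sp.support.items():
            counts.setdefault(tri, {})[sp.label] = n
    pmap: ProbabilityMap = {}
    for tri, by_label in counts.items():
        total = sum(by_label.values())
        entries = [(lab, n / total) for lab, n in by_label.items()]
        entries.sort(key=lambda e: (-e[1], e[0]))
        pmap[tri] = entries
    return pmap


def remove_small_subparcels(subparcels: Sequence[Subparcel], size_thr: float,
                            surface: Optional[LabeledSurface] = None,
                            rule: str = "mean_subparcel"
                            ) -> tuple[list[Subparcel], list[str]]:
    """Drop, per region, sub-parcels below the size threshold.

    ``mean_subparcel``: size < size_thr * mean sub-parcel size in the region.
    ``region_fraction``: size < size_thr * number of triangles in the region
    (requires ``surface``).
    """
    if not (0.0 < size_thr < 1.0):
        raise ValueError("size_thr must lie in (0, 1)")
    by_region: dict[int, list[Subparcel]] = {}
    for sp in subparcels:
        by_region.setdefault(sp.region, []).append(sp)
    keep: list[Subparcel] = []
    removed: list[str] = []
    for region, sps in by_region.items():
        if rule == "mean_subparcel":
            cutoff = size_thr * (sum(sp.size for sp in sps) / len(sps))
        elif rule == "region_fraction":
            if surface is None:
                raise ValueError("region_fraction rule needs the surface")
            cutoff = size_thr * len(surface.region_triangles(region))
        else:
            raise ValueError(f"unknown size rule {rule!r}")
        for sp in sps:
            if sp.size < cutoff:
                removed.append(sp.name)
            else:
                keep.append(sp)
    keep.sort(key=lambda sp: sp.label)
    if removed:
        log.info("remove_small_subparcels: removed %d sub-parcels", len(removed))
    return keep, removed


def compute_density_centers(pmap: ProbabilityMap, dc_thr: float
                            ) -> dict[int, set[int]]:
    """Triangle sets where each sub-parcel's probability reaches ``dc_thr``."""
    if not (0.0 < dc_thr < 1.0):
        raise ValueError("dc_thr must lie in (0, 1)")
    centers: dict[int, set[int]] = {}
    for tri, entries in pmap.items():
        for lab, p in entries:
            if p >= dc_thr:
                centers.setdefault(lab, set()).add(tri)
    return centers


def compute_idc(dc_i: set[int], dc_j: set[int]) -> float:
    """Density-center overlap normalized by the smaller center; 0 if either empty."""
    if not dc_i or not dc_j:
        return 0.0
    return len(dc_i & dc_j) / min(len(dc_i), len(dc_j))


def build_merge_graph(candidates: Sequence[Subparcel],
                      density_centers: dict[int, set[int]],
                      idc_thr: float) -> nx.Graph:
    """Overlap graph for one region's candidates; isolated vertices excluded."""
    if not (0.0 < idc_thr < 1.0):
        raise ValueError("idc_thr must lie in (0, 1)")
    g = nx.Graph()
    labs = [sp.label for sp in candidates]
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            idc = compute_idc(density_centers.get(a, set()),
                              density_centers.get(b, set()))
            if idc >= idc_thr:
                g.add_edge(a, b, idc=idc)
    return g


def enumerate_maximal_cliques(g: nx.Graph) -> list[tuple[int, ...]]:
    """All maximal cliques, size descending, then lexicographic members."""
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)] if g.number_of_nodes() else []
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def merge_cliques(candidates: Sequence[Subparcel],
                  cliques: Sequence[tuple[int, ...]]
                  ) -> tuple[list[Subparcel], list[tuple[tuple[int, ...], str]]]:
    """Greedy fusion of sorted cliques.

    A clique fuses the subset of its members not yet consumed by an earlier
    (larger) clique, and only if at least two remain.  Returns the resulting
    sub-parcels (merged ones carry fresh provisional labels) and a merge log.
    """
    by_label = {sp.label: sp for sp in candidates}
    consumed: set[int] = set()
    merged: list[Subparcel] = []
    merges: list[tuple[tuple[int, ...], str]] = []
    next_label = max(by_label) + 1 if by_label else 0
    for clique in cliques:
        avail = tuple(lab for lab in clique if lab not in consumed)
        if len(avail) < 2:
            continue
        support: dict[int, int] = {}
        for lab in avail:
            for tri, n in by_label[lab].support.items():
                support[tri] = support.get(tri, 0) + n
        name = "+".join(sorted(by_label[lab].name for lab in avail))
        sp = Subparcel(label=next_label, name=name,
                       region=by_label[avail[0]].region, support=support)
        next_label += 1
        merged.append(sp)
        merges.append((avail, name))
        consumed.update(avail)
    out = [sp for sp in candidates if sp.label not in consumed] + merged
    out.sort(key=lambda sp: sp.label)
    return out, merges


def relabel(subparcels: Sequence[Subparcel]) -> list[Subparcel]:
    """Assign deterministic dense labels 0..n-1 ordered by (region, name)."""
    ordered = sorted(subparcels, key=lambda sp: (sp.region, sp.name))
    return [replace(sp, label=i) for i, sp in enumerate(ordered)]


def harden(pmap: ProbabilityMap, n_triangles: int,
           subparcels: Sequence[Subparcel]) -> HardParcellation:
    """Most probable label per triangle; triangles with no counts unlabeled."""
    labels = np.full(n_triangles, UNLABELED, dtype=np.int64)
    for tri, entries in pmap.items():
        labels[tri] = entries[0][0]
    return HardParcellation(
        labels=labels,
        label_table={sp.label: sp.name for sp in subparcels},
        regions={sp.label: sp.region for sp in subparcels},
    )


@dataclass
class ParcellationResult:
    subparcels: list[Subparcel]
    pmap: ProbabilityMap
    hard: HardParcellation
    provenance: dict


def parcellate(filtered_per_subject: Sequence[Sequence[FilteredBundle]],
               surface: LabeledSurface, atlas: BundleAtlas,
               cfg: PipelineConfig) -> ParcellationResult:
    """Full Step 5: preliminary sub-parcels through hard parcellation."""
    prelim = build_preliminary_subparcels(filtered_per_subject, surface, atlas)
    candidates, removed = remove_small_subparcels(
        prelim, cfg.size_thr, surface=surface, rule=cfg.size_rule)
    pmap = compute_probability_maps(candidates)
    centers = compute_density_centers(pmap, cfg.dc_thr)

    by_region: dict[int, list[Subparcel]] = {}
    for sp in candidates:
        by_region.setdefault(sp.region, []).append(sp)
    final: list[Subparcel] = []
    merge_log: list[tuple[tuple[int, ...], str]] = []
    for region in sorted(by_region):
        g = build_merge_graph(by_region[region], centers, cfg.idc_thr)
        cliques = enumerate_maximal_cliques(g)
        merged, merges = merge_cliques(by_region[region], cliques)
        final.extend(merged)
        merge_log.extend(merges)

    final = relabel(final)
    pmap_final = compute_probability_maps(final)
    hard = harden(pmap_final, surface.n_triangles, final)
    provenance = {
        "n_preliminary": len(prelim),
        "n_after_size_filter": len(candidates),
        "removed_small": removed,
        "n_merges": len(merge_log),
        "merge_log": [{"members": list(m), "name": n} for m, n in merge_log],
        "n_final": len(final),
    }
    return ParcellationResult(subparcels=final, pmap=pmap_final, hard=hard,
                              provenance=provenance)
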