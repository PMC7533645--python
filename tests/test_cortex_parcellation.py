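import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortiparcel.cortex_parcellation import (
    Subparcel,
    UNLABELED,
    build_merge_graph,
    build_preliminary_subparcels,
    compute_density_centers,
    compute_idc,
    compute_probability_maps,
    enumerate_maximal_cliques,
    harden,
    merge_cliques,
    parcellate,
    relabel,
    remove_small_subparcels,
)
from cortiparcel.data_model_io import Bundle, BundleAtlas, LabeledSurface
from cortiparcel.fiber_filtering import FilteredBundle, OrientedRecord
from cortiparcel.synthetic_cohort import icosphere

from oracles import idc_oracle, maximal_cliques_bruteforce


@pytest.fixture(scope="module")
def flat_surface():
    # all triangles in one region so neighborhood clipping is inert
    verts, faces = icosphere(1)
    return LabeledSurface(vertices=verts * 50, triangles=faces,
                          vertex_labels=np.zeros(len(verts), dtype=int))


def _atlas_one_bundle(region_start=0, region_end=0):
    ts = np.linspace(0, 1, 21)
    f = np.column_stack([ts, ts, ts])
    return BundleAtlas(bundles=[Bundle(
        name="lh_R0-R0_0", fibers=[f], threshold_mm=5.0, centroid=f,
        region_start=region_start, region_end=region_end, hemisphere="left")])


def _rec(fid, ta, tb, name="lh_R0-R0_0"):
    return OrientedRecord(fiber_id=fid, bundle_name=name, tri_start=ta, tri_end=tb)


class TestBuildPreliminary:
    def test_single_fiber_counts_neighborhood(self, flat_surface):
        atlas = _atlas_one_bundle()
        fb = FilteredBundle("lh_R0-R0_0", [_rec(0, 10, 40)])
        sps = build_preliminary_subparcels([[fb]], flat_surface, atlas)
        assert len(sps) == 2
        start = next(sp for sp in sps if sp.name.endswith(".start"))
        expected = {10} | set(flat_surface.vertex_adjacency[10])
        assert set(start.support) == expected
        assert all(v == 1 for v in start.support.values())

    def test_additivity_across_subjects(self, flat_surface):
        atlas = _atlas_one_bundle()
        subjects = [[FilteredBundle("lh_R0-R0_0", [_rec(0, 10, 40)])]
                    for _ in range(3)]
        sps = build_preliminary_subparcels(subjects, flat_surface, atlas)
        start = next(sp for sp in sps if sp.name.endswith(".start"))
        assert start.support[10] == 3

    def test_region_clipping(self):
        verts, faces = icosphere(1)
        labels = np.zeros(len(verts), dtype=int)
        labels[verts[:, 2] > 0] = 1
        surf = LabeledSurface(vertices=verts * 50, triangles=faces,
                              vertex_labels=labels)
        tri0 = int(np.flatnonzero(surf.triangle_labels == 0)[0])
        atlas = _atlas_one_bundle(region_start=0, region_end=0)
        fb = FilteredBundle("lh_R0-R0_0", [_rec(0, tri0, tri0)])
        sps = build_preliminary_subparcels([[fb]], surf, atlas)
        for sp in sps:
            for t in sp.support:
                assert surf.triangle_labels[t] == sp.region

    def test_hand_computed_accumulation(self, flat_surface):
        # 2 bundles x 10 fibers x 4 subjects with known end triangles
        ts = np.linspace(0, 1, 21)
        f = np.column_stack([ts, ts, ts])
        atlas = BundleAtlas(bundles=[
            Bundle(name=f"lh_R0-R0_{i}", fibers=[f], threshold_mm=5.0,
                   centroid=f, region_start=0, region_end=0, hemisphere="left")
            for i in range(2)])
        rng = np.random.default_rng(8)
        nt = flat_surface.n_triangles
        subjects = []
        expected: dict[str, dict[int, int]] = {}
        for _ in range(4):
            bundles = []
            for bi in range(2):
                recs = []
                for fid in range(10):
                    ta, tb = int(rng.integers(nt)), int(rng.integers(nt))
                    recs.append(_rec(fid, ta, tb, name=f"lh_R0-R0_{bi}"))
                    for key, tri in ((f"lh_R0-R0_{bi}.start", ta),
                                     (f"lh_R0-R0_{bi}.end", tb)):
                        for t2 in {tri} | set(flat_surface.vertex_adjacency[tri]):
                            expected.setdefault(key, {})
                            expected[key][t2] = expected[key].get(t2, 0) + 1
                bundles.append(FilteredBundle(f"lh_R0-R0_{bi}", recs))
            subjects.append(bundles)
        sps = build_preliminary_subparcels(subjects, flat_surface, atlas)
        assert {sp.name: sp.support for sp in sps} == expected


class TestProbabilityMaps:
    def test_single_subparcel_prob_one(self):
        sp = Subparcel(label=0, name="a", region=0, support={3: 7, 4: 1})
        pmap = compute_probability_maps([sp])
        assert pmap[3] == [(0, 1.0)]
        assert pmap[4] == [(0, 1.0)]

    def test_counts_normalized(self):
        a = Subparcel(label=0, name="a", region=0, support={5: 3})
        b = Subparcel(label=1, name="b", region=0, support={5: 1})
        pmap = compute_probability_maps([a, b])
        assert pmap[5] == [(0, 0.75), (1, 0.25)]

    def test_sum_to_one_invariant(self, default_run):
        for entries in default_run.result.pmap.values():
            assert sum(p for _, p in entries) == pytest.approx(1.0, abs=1e-9)
            probs = [p for _, p in entries]
            assert probs == sorted(probs, reverse=True)

    def test_tie_broken_by_label(self):
        a = Subparcel(label=3, name="a", region=0, support={5: 2})
        b = Subparcel(label=1, name="b", region=0, support={5: 2})
        pmap = compute_probability_maps([a, b])
        assert pmap[5] == [(1, 0.5), (3, 0.5)]


class TestRemoveSmall:
    def _sps(self, sizes, region=0, start_label=0):
        return [Subparcel(label=start_label + i, name=f"sp{start_label + i}",
                          region=region,
                          support={t: 1 for t in range(n)})
                for i, n in enumerate(sizes)]

    def test_all_equal_kept(self):
        keep, removed = remove_small_subparcels(self._sps([100, 100, 100]), 0.10)
        assert len(keep) == 3 and removed == []

    def test_small_removed_under_mean_rule(self):
        # mean(100, 100, 5) = 68.33; 5 < 6.833 -> removed
        keep, removed = remove_small_subparcels(self._sps([100, 100, 5]), 0.10)
        assert [sp.size for sp in keep] == [100, 100]
        assert removed == ["sp2"]

    def test_tiny_threshold_keeps_all(self):
        keep, removed = remove_small_subparcels(self._sps([100, 100, 5]), 1e-9)
        assert len(keep) == 3

    def test_region_fraction_rule(self, flat_surface):
        # region 0 has all triangles; cutoff = 0.10 * n_triangles
        nt = flat_surface.n_triangles
        small = max(1, nt // 20)  # below 10%
        big = nt // 2
        keep, removed = remove_small_subparcels(
            self._sps([big, small]), 0.10, surface=flat_surface,
            rule="region_fraction")
        assert [sp.size for sp in keep] == [big]
        assert len(removed) == 1

    def test_regions_independent(self):
        sps = self._sps([100, 100, 5]) + self._sps([5, 5], region=1,
                                                   start_label=10)
        keep, removed = remove_small_subparcels(sps, 0.10)
        # region 1's sub-parcels are all equal -> kept
        assert {sp.label for sp in keep} == {0, 1, 10, 11}


class TestDensityCenters:
    def test_prob_one_full_support(self):
        sp = Subparcel(label=0, name="a", region=0, support={1: 2, 2: 5})
        pmap = compute_probability_maps([sp])
        dc = compute_density_centers(pmap, 0.3)
        assert dc[0] == {1, 2}

    def test_threshold_excludes(self):
        a = Subparcel(label=0, name="a", region=0, support={5: 1})
        b = Subparcel(label=1, name="b", region=0, support={5: 3})
        pmap = compute_probability_maps([a, b])
        dc = compute_density_centers(pmap, 0.30)
        assert 5 not in dc.get(0, set())  # p = 0.25 < 0.30
        assert 5 in dc[1]

    def test_monotone_shrink_with_threshold(self, default_run):
        pmap = default_run.result.pmap
        prev = None
        for thr in (0.1, 0.2, 0.3, 0.5, 0.7):
            dc = compute_density_centers(pmap, thr)
            if prev is not None:
                for lab, tris in dc.items():
                    assert tris <= prev.get(lab, set())
            prev = dc


class TestIdc:
    def test_self_overlap_one(self):
        assert compute_idc({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_zero(self):
        assert compute_idc({1, 2}, {3, 4}) == 0.0

    def test_worked_example(self):
        assert compute_idc({1, 2, 3, 4}, {3, 4, 5, 6, 7, 8}) == 0.5

    def test_empty_zero(self):
        assert compute_idc(set(), {1}) == 0.0
        assert compute_idc({1}, set()) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_properties_and_oracle(self, a, b):
        got = compute_idc(a, b)
        assert got == compute_idc(b, a)
        assert 0.0 <= got <= 1.0
        assert got == pytest.approx(idc_oracle(a, b))


class TestMergeGraph:
    def _sp(self, label):
        return Subparcel(label=label, name=f"sp{label}", region=0,
                         support={label: 1})

    def test_boundary_threshold_inclusive(self):
        dcs = {0: {1, 2, 3, 4, 5, 6, 7, 8, 9, 10}, 1: {1, 2, 3, 4, 5, 11, 12, 13, 14, 15}}
        # idc = 5/10 = 0.5 exactly
        g = build_merge_graph([self._sp(0), self._sp(1)], dcs, 0.5)
        assert g.has_edge(0, 1)

    def test_triangle_of_overlaps(self):
        dcs = {0: {1, 2}, 1: {2, 3}, 2: {1, 3}}
        g = build_merge_graph([self._sp(i) for i in range(3)], dcs, 0.4)
        assert set(g.edges) == {(0, 1), (0, 2), (1, 2)}

    def test_isolated_subparcels_excluded(self):
        dcs = {0: {1, 2}, 1: {1, 2}, 2: {99}}
        g = build_merge_graph([self._sp(i) for i in range(3)], dcs, 0.5)
        assert 2 not in g.nodes

    def test_near_one_threshold_only_identical(self):
        dcs = {0: {1, 2, 3, 4}, 1: {1, 2, 3, 4}, 2: {1, 2, 3, 9}}
        g = build_merge_graph([self._sp(i) for i in range(3)], dcs, 0.99)
        assert g.has_edge(0, 1)
        assert not g.has_edge(0, 2)


class TestMaximalCliques:
    def test_triangle_graph(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3)])
        assert enumerate_maximal_cliques(g) == [(1, 2, 3)]

    def test_path_graph(self):
        g = nx.Graph([(1, 2), (2, 3)])
        assert enumerate_maximal_cliques(g) == [(1, 2), (2, 3)]

    def test_random_graphs_match_bruteforce(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            p = rng.uniform(0.1, 0.9)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() == 0:
                continue
            got = enumerate_maximal_cliques(g)
            want = maximal_cliques_bruteforce(g.nodes, g.edges)
            assert got == want


class TestMergeCliques:
    def _sp(self, label, support):
        return Subparcel(label=label, name=f"sp{label}", region=0,
                         support=dict(support))

    def test_single_clique_sums_support(self):
        cands = [self._sp(0, {1: 1, 2: 1}), self._sp(1, {2: 2}),
                 self._sp(2, {3: 5})]
        out, merges = merge_cliques(cands, [(0, 1, 2)])
        assert len(out) == 1
        assert out[0].support == {1: 1, 2: 3, 3: 5}
        assert merges[0][0] == (0, 1, 2)

    def test_consumed_members_skipped(self):
        cands = [self._sp(i, {i: 1}) for i in range(4)]
        out, merges = merge_cliques(cands, [(0, 1, 2), (1, 3)])
        # second clique reduces to {3}: fewer than 2 members left -> no fusion
        labels = sorted(sp.label for sp in out)
        assert len(merges) == 1
        assert 3 in labels  # d stays unmerged
        assert len(out) == 2  # merged(0,1,2) + 3

    def test_no_cliques_identity(self):
        cands = [self._sp(i, {i: 1}) for i in range(3)]
        out, merges = merge_cliques(cands, [])
        assert out == cands and merges == []


class TestHarden:
    def test_argmax_label(self):
        a = Subparcel(label=0, name="a", region=0, support={5: 3})
        b = Subparcel(label=1, name="b", region=0, support={5: 1})
        pmap = compute_probability_maps([a, b])
        hp = harden(pmap, 10, [a, b])
        assert hp.labels[5] == 0

    def test_no_counts_unlabeled(self):
        a = Subparcel(label=0, name="a", region=0, support={5: 3})
        hp = harden(compute_probability_maps([a]), 10, [a])
        assert hp.labels[7] == UNLABELED

    def test_full_fixture_argmax_oracle(self, default_run):
        pmap = default_run.result.pmap
        labels = default_run.result.hard.labels
        for tri in range(len(labels)):
            if tri in pmap:
                best = max(pmap[tri], key=lambda e: (e[1], -e[0]))
                assert labels[tri] == best[0]
            else:
                assert labels[tri] == UNLABELED


class TestParcellateEndToEnd:
    def test_relabel_dense_and_deterministic(self, default_run):
        labels = [sp.label for sp in default_run.result.subparcels]
        assert labels == list(range(len(labels)))

    def test_supports_stay_in_region(self, default_run):
        surf = default_run.cohort.surface
        for sp in default_run.result.subparcels:
            for t in sp.support:
                assert surf.triangle_labels[t] == sp.region

    def test_merge_only_within_region(self, sweep_cohort, sweep_filtered):
        from cortiparcel.data_model_io import PipelineConfig

        result = parcellate(sweep_filtered, sweep_cohort.surface,
                            sweep_cohort.atlas, PipelineConfig())
        prelim_regions = {}
        for sp in result.subparcels:
            for t in sp.support:
                assert sweep_cohort.surface.triangle_labels[t] == sp.region

    def test_relabel_orders_by_region_then_name(self):
        sps = [Subparcel(label=9, name="b", region=1, support={1: 1}),
               Subparcel(label=7, name="a", region=0, support={2: 1}),
               Subparcel(label=8, name="c", region=0, support={3: 1})]
        out = relabel(sps)
        assert [(sp.label, sp.name) for sp in out] == [(0, "a"), (1, "c"), (2, "b")]
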