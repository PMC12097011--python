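"""Vessel segmentation: region growing vs a flood-fill oracle, sinusoid
extraction, and companion-proximity vein classification."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hepamorph.morphometry as mm
import hepamorph.phantom as ph
import hepamorph.vessels as vs
from hepamorph.grid import VoxelGrid


def bfs_flood_fill(data, seed_indices, low, high):
    """Independent breadth-first flood-fill oracle (26-connectivity)."""
    out = np.zeros(data.shape, np.int32)
    for i, pos in enumerate(seed_indices):
        if not (low <= data[pos] <= high):
            raise ValueError("seed outside window")
        if out[pos] != 0:
            continue
        out[pos] = i + 1
        q = deque([pos])
        while q:
            c = q.popleft()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        n = (c[0] + dx, c[1] + dy, c[2] + dz)
                        if (
                            all(0 <= v < s for v, s in zip(n, data.shape))
                            and out[n] == 0
                            and low <= data[n] <= high
                        ):
                            out[n] = i + 1
                            q.append(n)
    return out


class TestRegionGrow:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_bfs_oracle_on_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 5, size=(12, 12, 12)).astype(float)
        low, high = 1.0, 3.0
        cand = np.argwhere((data >= low) & (data <= high))
        if len(cand) == 0:
            return
        seed_idx = [tuple(int(v) for v in cand[rng.integers(len(cand))]) for _ in range(3)]
        g = VoxelGrid(data, (1.0,) * 3)
        seeds = [vs.SeedPoint(tuple(float(v) for v in s)) for s in seed_idx]
        mine = vs.region_grow(g, seeds, low, high, 26).data
        oracle = bfs_flood_fill(data, seed_idx, low, high)
        assert np.array_equal(mine, oracle)

    def test_seeded_cylinder_segmented_exactly(self):
        tree = [ph.Branch(np.array([[10.0, 20.0, 20.0], [50.0, 20.0, 20.0]]), radius=6.0)]
        mask = ph.rasterize_tree(tree, (60, 40, 40), (1.0,) * 3).data > 0
        gray = VoxelGrid(np.where(mask, 200.0, 50.0), (1.0,) * 3)
        out = vs.region_grow(gray, [vs.SeedPoint((30.0, 20.0, 20.0))], 150, 255)
        assert np.array_equal(out.data > 0, mask)

    def test_only_seeded_tube_labelled(self):
        data = np.full((40, 40, 40), 50.0)
        data[5:10, :, :] = 200.0   # tube A
        data[30:35, :, :] = 200.0  # tube B, disjoint
        g = VoxelGrid(data, (1.0,) * 3)
        out = vs.region_grow(g, [vs.SeedPoint((7.0, 20.0, 20.0))], 150, 255).data
        assert (out[5:10] == 1).all() and (out[30:35] == 0).all()

    def test_constant_volume_fully_labelled_at_tight_window(self):
        g = VoxelGrid(np.full((20, 20, 20), 7.0), (1.0,) * 3)
        out = vs.region_grow(g, [vs.SeedPoint((10.0, 10.0, 10.0))], 7, 7)
        assert (out.data == 1).all()

    def test_seed_outside_window_names_seed(self):
        g = VoxelGrid(np.full((10, 10, 10), 5.0), (1.0,) * 3)
        with pytest.raises(ValueError, match="seed 0"):
            vs.region_grow(g, [vs.SeedPoint((5.0, 5.0, 5.0))], 10, 20)

    def test_first_seed_wins_contested_component(self):
        g = VoxelGrid(np.full((10, 10, 10), 5.0), (1.0,) * 3)
        seeds = [vs.SeedPoint((2.0, 2.0, 2.0)), vs.SeedPoint((8.0, 8.0, 8.0))]
        out = vs.region_grow(g, seeds, 0, 10)
        assert (out.data == 1).all()

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_enlarging_window_never_shrinks_output(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 6, size=(10, 10, 10)).astype(float)
        data[5, 5, 5] = 3.0
        g = VoxelGrid(data, (1.0,) * 3)
        seeds = [vs.SeedPoint((5.0, 5.0, 5.0))]
        narrow = vs.region_grow(g, seeds, 2, 4).data > 0
        wide = vs.region_grow(g, seeds, 1, 5).data > 0
        assert np.all(wide[narrow])


class TestSegmentSinusoids:
    def test_full_vessel_subtraction_gives_empty(self):
        data = np.full((20, 20, 20), 200.0)
        g = VoxelGrid(data, (1.0,) * 3)
        vessel = g.with_data(np.ones_like(data, dtype=np.int8), kind="labels")
        out = vs.segment_sinusoids(g, 150, 255, vessel)
        assert not out.data.any()

    def test_min_volume_filter_removes_everything_when_too_large(self):
        data = np.full((20, 20, 20), 50.0)
        data[5:8, 5:8, 5:8] = 200.0
        g = VoxelGrid(data, (1.0,) * 3)
        vessel = g.with_data(np.zeros_like(data, dtype=np.int8), kind="labels")
        out = vs.segment_sinusoids(g, 150, 255, vessel, min_volume_um3=1e6)
        assert not out.data.any()

    def test_output_disjoint_from_vessel_mask(self, default_phantom):
        cfg, truth, gray = default_phantom
        vessel = truth.labels.with_data(truth.mask(1, 2, 3, 4).astype(np.int8), "labels")
        out = vs.segment_sinusoids(gray, 165, 255, vessel, min_volume_um3=20)
        assert not np.logical_and(out.data > 0, vessel.data > 0).any()

    def test_phantom_sinusoid_recovery_iou(self):
        # noise-free contrast with modest noise: recovered mesh IoU >= 0.9
        cfg = ph.PhantomConfig(
            shape=(96, 96, 96), seed=31,
            steatosis_params=ph.SteatosisParams(band_probabilities=(0.0,) * 4),
            intensity_model=ph.IntensityModel(noise_sd=5.0),
        )
        truth, gray = ph.generate_phantom(cfg)
        vessel = truth.labels.with_data(truth.mask(1, 2, 3, 4).astype(np.int8), "labels")
        out = vs.segment_sinusoids(gray, 135.0, 255.0, vessel, min_volume_um3=10)
        import hepamorph.steatosis as stx

        truth_sin = truth.labels.with_data(truth.mask(5).astype(np.int8), "labels")
        iou = stx.evaluate_overlap(out, truth_sin)["iou"]
        assert iou >= 0.9

    def test_grid_mismatch_rejected(self):
        g = VoxelGrid(np.zeros((10, 10, 10)), (1.0,) * 3)
        v = VoxelGrid(np.zeros((8, 8, 8), np.int8), (1.0,) * 3, kind="labels")
        with pytest.raises(ValueError):
            vs.segment_sinusoids(g, 0, 1, v)


def _tube_graph_and_companion(offset_um):
    """A straight vein branch with (or without) a parallel companion tube."""
    vein = [ph.Branch(np.array([[10.0, 40.0, 40.0], [90.0, 40.0, 40.0]]), radius=8.0)]
    vein_mask = ph.rasterize_tree(vein, (100, 80, 80), (1.0,) * 3)
    skel = mm.skeletonize(vein_mask)
    graph = mm.build_graph(skel, prune_below_um=5)
    comp = np.zeros((100, 80, 80), np.int8)
    if offset_um is not None:
        comp_tree = [ph.Branch(
            np.array([[10.0, 40.0 + offset_um, 40.0], [90.0, 40.0 + offset_um, 40.0]]),
            radius=3.0)]
        comp = ph.rasterize_tree(comp_tree, (100, 80, 80), (1.0,) * 3).data
    return graph, VoxelGrid(np.asarray(comp, np.int8), (1.0,) * 3, kind="labels")


class TestClassifyVeinBranches:
    def test_empty_companion_mask_gives_all_central(self):
        graph, comp = _tube_graph_and_companion(None)
        assert vs.classify_vein_branches(graph, comp, 40.0, 0.5) == ["central"] * len(
            graph.edges
        )

    def test_parallel_companion_classifies_portal(self):
        graph, comp = _tube_graph_and_companion(20.0)
        assert set(vs.classify_vein_branches(graph, comp, 40.0, 0.5)) == {"portal"}

    def test_distant_companion_classifies_central(self):
        graph, comp = _tube_graph_and_companion(20.0)
        assert set(vs.classify_vein_branches(graph, comp, 5.0, 0.5)) == {"central"}

    def test_zero_threshold_is_any_contact(self):
        graph, comp = _tube_graph_and_companion(20.0)
        assert set(vs.classify_vein_branches(graph, comp, 21.0, 0.0)) == {"portal"}

    def test_mixed_trees_classified_with_high_branch_accuracy(self):
        # portal tree with companion tubes at 20 µm, a central tree far
        # from any companion; search radius 40 µm, threshold 0.5
        shape = (160, 120, 120)
        portal = [
            ph.Branch(np.array([[130.0, 20.0, 60.0], [130.0, 100.0, 60.0]]), radius=10.0),
            ph.Branch(np.array([[130.0, 60.0, 60.0], [145.0, 60.0, 20.0]]), radius=7.0),
        ]
        central = [
            ph.Branch(np.array([[30.0, 20.0, 60.0], [30.0, 100.0, 60.0]]), radius=10.0),
            ph.Branch(np.array([[30.0, 60.0, 60.0], [15.0, 60.0, 100.0]]), radius=7.0),
        ]
        companions = [
            ph.Branch(b.points + np.array([0.0, 0.0, 0.0]) + 20.0 * np.array([1, 0, 0]),
                      radius=3.0)
            for b in portal
        ]
        comp_mask = ph.rasterize_tree(companions, shape, (1.0,) * 3)
        expected = []
        graphs = []
        for tree, kind in ((central, "central"), (portal, "portal")):
            mask = ph.rasterize_tree(tree, shape, (1.0,) * 3)
            graph = mm.build_graph(mm.skeletonize(mask), prune_below_um=8)
            graphs.append(graph)
            expected += [kind] * len(graph.edges)
        classes = []
        for graph in graphs:
            classes += vs.classify_vein_branches(graph, comp_mask, 40.0, 0.5)
        assert len(classes) > 0
        accuracy = np.mean([c == e for c, e in zip(classes, expected)])
        assert accuracy >= 0.95


class TestSplitBySeed:
    def _two_component_grid(self):
        lab = np.zeros((40, 40, 40), np.int32)
        lab[5:15, 5:15, 5:15] = 1
        lab[25:35, 25:35, 25:35] = 1
        return VoxelGrid(lab, (1.0,) * 3, kind="labels")

    def test_components_assigned_by_seed_type(self):
        g = self._two_component_grid()
        seeds = [vs.SeedPoint((10.0, 10.0, 10.0), "central"),
                 vs.SeedPoint((30.0, 30.0, 30.0), "portal")]
        out = vs.split_by_seed(g, seeds)
        assert out["central"].data[10, 10, 10] and not out["central"].data[30, 30, 30]
        assert out["portal"].data[30, 30, 30] and not out["portal"].data[10, 10, 10]

    def test_conflicting_seeds_rejected(self):
        g = self._two_component_grid()
        seeds = [vs.SeedPoint((10.0, 10.0, 10.0), "central"),
                 vs.SeedPoint((12.0, 12.0, 12.0), "portal")]
        with pytest.raises(ValueError, match="conflicting"):
            vs.split_by_seed(g, seeds)

    def test_orphan_component_rejected(self):
        g = self._two_component_grid()
        with pytest.raises(ValueError, match="without any seed"):
            vs.split_by_seed(g, [vs.SeedPoint((10.0, 10.0, 10.0), "central")])

    def test_phantom_split_matches_truth(self, default_phantom):
        cfg, truth, _ = default_phantom
        cv = truth.mask(1)
        pv = truth.mask(2)
        both = VoxelGrid((cv | pv).astype(np.int32), truth.labels.spacing, kind="labels")
        seeds = [
            vs.SeedPoint(tuple(truth.trees["central"][0].points[0]), "central"),
            vs.SeedPoint(tuple(truth.trees["portal"][0].points[0]), "portal"),
        ]
        out = vs.split_by_seed(both, seeds)
        assert np.array_equal(out["central"].data > 0, cv)
        assert np.array_equal(out["portal"].data > 0, pv)
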