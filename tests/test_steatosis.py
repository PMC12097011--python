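"""Voxel-classifier stand-in: features, training curves, prediction,
overlap metrics, and mask-times-gray extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_strat

import hepamorph.phantom as ph
import hepamorph.spatial as sp
import hepamorph.steatosis as st
from hepamorph.grid import VoxelGrid


def _separable_phantom(seed, shape=(64, 64, 64), noise_sd=8.0):
    """Two-intensity phantom: bright target blob on dark background."""
    rng = np.random.default_rng(seed)
    x, y, z = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    cx, cy, cz = (rng.uniform(0.3, 0.7) * s for s in shape)
    r = 0.28 * min(shape)
    truth = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 < r**2
    gray = np.where(truth, 150.0, 80.0) + rng.normal(0, noise_sd, shape)
    return VoxelGrid(gray.astype(np.float32), (1.0,) * 3), truth


def _annotate(truth, fraction, seed):
    rng = np.random.default_rng(seed)
    ann = np.zeros(truth.shape, np.int8)
    for code, sel in ((st.TARGET, truth), (st.BACKGROUND, ~truth)):
        idx = np.flatnonzero(sel.ravel())
        take = rng.choice(idx, size=max(1, int(len(idx) * fraction)), replace=False)
        ann.ravel()[take] = code
    return ann


class TestExtractFeatures:
    def test_constant_volume_has_zero_texture_features(self):
        g = VoxelGrid(np.full((24, 24, 24), 100.0, np.float32), (1.0,) * 3)
        feats = st.extract_features(g, (2.0, 4.0))
        assert feats.shape == (24, 24, 24, 5)
        assert np.allclose(feats[..., 1], 0.0, atol=1e-3)  # sd at scale 2
        assert np.allclose(feats[..., 3], 0.0, atol=1e-3)  # sd at scale 4
        assert np.allclose(feats[..., 4], 0.0)  # local range

    def test_checkerboard_has_higher_local_sd_than_flat_region(self):
        data = np.full((32, 32, 32), 100.0, np.float32)
        x, y, z = np.meshgrid(*(np.arange(32),) * 3, indexing="ij")
        checker = ((x + y + z) % 2).astype(np.float32) * 60
        data[:, :, 16:] += checker[:, :, 16:]
        g = VoxelGrid(data, (1.0,) * 3)
        feats = st.extract_features(g, (2.0,))
        assert feats[10, 10, 24, 1] > feats[10, 10, 4, 1] + 10

    def test_scale_below_spacing_rejected(self):
        g = VoxelGrid(np.zeros((8, 8, 8), np.float32), (2.0,) * 3)
        with pytest.raises(ValueError):
            st.extract_features(g, (1.0,))

    def test_empty_scales_rejected(self):
        g = VoxelGrid(np.zeros((8, 8, 8), np.float32), (1.0,) * 3)
        with pytest.raises(ValueError):
            st.extract_features(g, ())


class TestTrain:
    def test_separable_phantom_reaches_99pct_val_accuracy(self):
        g, truth = _separable_phantom(0)
        feats = st.extract_features(g, (1.5, 4.0))
        labels = g.with_data(_annotate(truth, 0.05, 1), kind="labels")
        clf, curves = st.train(feats, labels, iterations=300, seed=0)
        assert curves.final_val_accuracy >= 0.99

    def test_training_deterministic_given_seed(self):
        g, truth = _separable_phantom(2, shape=(32, 32, 32))
        feats = st.extract_features(g, (1.5,))
        labels = g.with_data(_annotate(truth, 0.1, 3), kind="labels")
        _, c1 = st.train(feats, labels, iterations=100, seed=7)
        _, c2 = st.train(feats, labels, iterations=100, seed=7)
        assert c1.loss == c2.loss
        assert c1.val_accuracy == c2.val_accuracy

    def test_final_val_accuracy_not_below_initial(self):
        g, truth = _separable_phantom(4, shape=(32, 32, 32))
        feats = st.extract_features(g, (1.5,))
        labels = g.with_data(_annotate(truth, 0.1, 5), kind="labels")
        _, curves = st.train(feats, labels, iterations=200, seed=1)
        assert curves.final_val_accuracy >= curves.val_accuracy[0]

    def test_zero_iterations_rejected(self):
        g, truth = _separable_phantom(5, shape=(16, 16, 16))
        feats = st.extract_features(g, (1.5,))
        labels = g.with_data(_annotate(truth, 0.2, 0), kind="labels")
        with pytest.raises(ValueError):
            st.train(feats, labels, iterations=0)

    def test_single_class_annotation_rejected(self):
        g, truth = _separable_phantom(6, shape=(16, 16, 16))
        feats = st.extract_features(g, (1.5,))
        ann = np.zeros(truth.shape, np.int8)
        ann[truth] = st.TARGET
        with pytest.raises(ValueError, match="target and background"):
            st.train(feats, g.with_data(ann, kind="labels"), iterations=10)

    def test_curves_iterations_strictly_increasing(self):
        g, truth = _separable_phantom(8, shape=(24, 24, 24))
        feats = st.extract_features(g, (1.5,))
        labels = g.with_data(_annotate(truth, 0.2, 1), kind="labels")
        _, curves = st.train(feats, labels, iterations=120, log_interval=50)
        assert curves.iteration == sorted(set(curves.iteration))
        assert all(0 <= a <= 1 for a in curves.val_accuracy + curves.val_iou)


class TestPredict:
    def test_raw_threshold_without_postprocessing(self):
        g, truth = _separable_phantom(9, shape=(32, 32, 32), noise_sd=2.0)
        feats = st.extract_features(g, (1.5,))
        labels = g.with_data(_annotate(truth, 0.2, 2), kind="labels")
        clf, _ = st.train(feats, labels, iterations=200, seed=0)
        mask = st.predict(clf, feats, g, closing_radius_um=0, min_component_um3=0)
        ov = st.evaluate_overlap(mask, g.with_data(truth.astype(np.int8), "labels"))
        assert ov["iou"] >= 0.9

    def test_min_component_above_largest_gives_empty(self):
        g, truth = _separable_phantom(10, shape=(32, 32, 32), noise_sd=2.0)
        feats = st.extract_features(g, (1.5,))
        labels = g.with_data(_annotate(truth, 0.2, 2), kind="labels")
        clf, _ = st.train(feats, labels, iterations=200, seed=0)
        mask = st.predict(clf, feats, g, min_component_um3=1e9)
        assert not mask.data.any()

    def test_feature_specification_mismatch_rejected(self):
        g, truth = _separable_phantom(11, shape=(16, 16, 16))
        feats = st.extract_features(g, (1.5,))
        labels = g.with_data(_annotate(truth, 0.2, 2), kind="labels")
        clf, _ = st.train(feats, labels, iterations=10, seed=0)
        wrong = st.extract_features(g, (1.5, 3.0))
        with pytest.raises(ValueError, match="mismatch"):
            st.predict(clf, wrong, g)

    def test_classifier_roundtrips_through_json(self, tmp_path):
        g, truth = _separable_phantom(12, shape=(24, 24, 24))
        feats = st.extract_features(g, (1.5,))
        labels = g.with_data(_annotate(truth, 0.2, 2), kind="labels")
        clf, _ = st.train(feats, labels, iterations=50, seed=0)
        clf.save(tmp_path / "clf.json")
        clf2 = st.VoxelClassifier.load(tmp_path / "clf.json")
        flat = feats.reshape(-1, feats.shape[-1])
        assert np.allclose(clf.scores(flat), clf2.scores(flat))

    def test_phantom_steatosis_iou_085_at_5pct_noise(self):
        # full phantom at noise 5% of the parenchyma/steatosis contrast
        cfg = ph.PhantomConfig(
            shape=(96, 96, 96), seed=17,
            intensity_model=ph.IntensityModel(noise_sd=3.5),
        )
        truth, gray = ph.generate_phantom(cfg)
        feats = st.extract_features(gray, (1.5, 4.0))
        target = truth.mask(6)
        labels = gray.with_data(_annotate(target, 0.05, 18), kind="labels")
        clf, _ = st.train(feats, labels, iterations=400, seed=18)
        mask = st.predict(clf, feats, gray)
        m = (np.asarray(mask.data) > 0) & ~truth.mask(1, 2, 3, 4)
        mask = mask.with_data(m.astype(np.int8), kind="labels")
        ov = st.evaluate_overlap(mask, gray.with_data(target.astype(np.int8), "labels"))
        assert ov["iou"] >= 0.85


class TestEvaluateOverlap:
    def test_identical_masks_all_ones(self, ball_grid):
        ov = st.evaluate_overlap(ball_grid, ball_grid)
        assert ov == {"accuracy": 1.0, "iou": 1.0, "dice": 1.0}

    def test_disjoint_masks_zero_iou(self):
        a = np.zeros((10, 10, 10), np.int8)
        b = np.zeros((10, 10, 10), np.int8)
        a[2, 2, 2] = 1
        b[7, 7, 7] = 1
        ga = VoxelGrid(a, (1.0,) * 3, kind="labels")
        gb = VoxelGrid(b, (1.0,) * 3, kind="labels")
        assert st.evaluate_overlap(ga, gb)["iou"] == 0.0

    def test_half_overlap_set_arithmetic(self):
        # |pred| = |truth| = 2k with overlap k: IoU = 1/3, Dice = 1/2
        a = np.zeros((10, 10, 10), np.int8)
        b = np.zeros((10, 10, 10), np.int8)
        a[0, 0, :4] = 1
        b[0, 0, 2:6] = 1
        ga = VoxelGrid(a, (1.0,) * 3, kind="labels")
        gb = VoxelGrid(b, (1.0,) * 3, kind="labels")
        ov = st.evaluate_overlap(ga, gb)
        assert ov["iou"] == pytest.approx(1 / 3)
        assert ov["dice"] == pytest.approx(1 / 2)

    def test_both_empty_defined_as_one(self):
        g = VoxelGrid(np.zeros((5, 5, 5), np.int8), (1.0,) * 3, kind="labels")
        assert st.evaluate_overlap(g, g)["iou"] == 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st_strat.integers(0, 1000))
    def test_symmetric_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.uniform(size=(8, 8, 8)) < 0.3).astype(np.int8)
        b = (rng.uniform(size=(8, 8, 8)) < 0.3).astype(np.int8)
        ga = VoxelGrid(a, (1.0,) * 3, kind="labels")
        gb = VoxelGrid(b, (1.0,) * 3, kind="labels")
        ab = st.evaluate_overlap(ga, gb)
        ba = st.evaluate_overlap(gb, ga)
        assert ab["iou"] == ba["iou"] and ab["dice"] == ba["dice"]


class TestApplyMask:
    def test_full_mask_is_identity(self):
        rng = np.random.default_rng(0)
        g = VoxelGrid(rng.uniform(0, 200, (10, 10, 10)).astype(np.float32), (1.0,) * 3)
        full = g.with_data(np.ones(g.shape, np.int8), kind="labels")
        assert np.array_equal(st.apply_mask(g, full).data, g.data)

    def test_empty_mask_zeroes_volume(self):
        rng = np.random.default_rng(1)
        g = VoxelGrid(rng.uniform(0, 200, (10, 10, 10)).astype(np.float32), (1.0,) * 3)
        empty = g.with_data(np.zeros(g.shape, np.int8), kind="labels")
        assert not st.apply_mask(g, empty).data.any()

    def test_sum_conserved_over_mask(self):
        rng = np.random.default_rng(2)
        g = VoxelGrid(rng.uniform(0, 200, (12, 12, 12)).astype(np.float32), (1.0,) * 3)
        m = (rng.uniform(size=g.shape) < 0.4).astype(np.int8)
        mask = g.with_data(m, kind="labels")
        out = st.apply_mask(g, mask)
        assert out.data.sum() == pytest.approx(g.data[m > 0].sum())

    def test_grid_mismatch_rejected(self):
        g = VoxelGrid(np.zeros((8, 8, 8), np.float32), (1.0,) * 3)
        m = VoxelGrid(np.zeros((9, 9, 9), np.int8), (1.0,) * 3, kind="labels")
        with pytest.raises(ValueError):
            st.apply_mask(g, m)


class TestEndToEndChain:
    def test_band_profile_recovered_through_full_chain(self):
        """Phantom → features → train → predict → band quantification
        recovers the programmed band fractions within ±0.07."""
        cfg = ph.PhantomConfig(shape=(128, 128, 128), seed=23,
                               intensity_model=ph.IntensityModel(noise_sd=5.0))
        truth, gray = ph.generate_phantom(cfg)
        feats = st.extract_features(gray, (1.5, 4.0))
        target = truth.mask(6)
        labels = gray.with_data(_annotate(target, 0.05, 24), kind="labels")
        clf, _ = st.train(feats, labels, iterations=400, seed=24)
        mask = st.predict(clf, feats, gray)
        vessels = truth.mask(1, 2, 3, 4)
        m = (np.asarray(mask.data) > 0) & ~vessels
        mask = mask.with_data(m.astype(np.int8), kind="labels")
        cv = truth.labels.with_data(truth.mask(1).astype(np.int8), kind="labels")
        dist = sp.surface_distance_field(cv)
        other = truth.labels.with_data(
            (vessels & ~truth.mask(1)).astype(np.int8), kind="labels")
        rep = sp.band_quantify(dist, mask, exclude_mask=other)
        programmed = np.asarray(cfg.steatosis_params.band_probabilities)
        measured = rep.fractions
        valid = rep.region_volume_um3 > 0.02 * rep.region_volume_um3.sum()
        assert valid.sum() >= 2  # bands truncated by the small volume are skipped
        assert np.all(np.abs(measured[valid] - programmed[valid]) <= 0.07)
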