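"""The two-stage detector: training behavior, Grad-CAM, scanning, segmentation.

Tests that need trained stages share the session-scoped ``trained_bundle``
fixture (both stages trained once on the default synthetic datasets).
"""

import numpy as np
import pytest

from temquant._minicnn import (Conv2D, Dense, GlobalAvgPool, ReLU, Sequential)
from temquant.models import (PatchClassifier, PatchSegmenter, VesicleDetector,
                             grad_cam_from_net)
from temquant.synth import (PixelImage, make_patch_dataset,
                            synthesize_vesicle_field)
from temquant.vesnet import (ModelBundle, TrainConfig, grad_cam,
                             scan_localize, segment_vesicles, train_stage)


def toy_patches(n=120, p=16, seed=0):
    """Linearly separable toy set: bright centred disk vs flat background."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.3, 0.02, size=(n, p, p))
    y = np.zeros(n, dtype=int)
    gy, gx = np.mgrid[0:p, 0:p]
    disk = (gy - p / 2) ** 2 + (gx - p / 2) ** 2 < (p / 4) ** 2
    for i in range(n // 2):
        X[i][disk] += 0.5
        y[i] = 1
    return X, y


class TestTrainConfig:
    def test_stage_defaults_follow_regimes(self):
        c1 = TrainConfig(stage=1).resolved()
        assert c1["mini_batch"] == 25 and c1["max_epoch"] == 500
        assert c1["augment_resize"] == 0.10 and c1["augment_shift_px"] == 0
        c2 = TrainConfig(stage=2).resolved()
        assert c2["mini_batch"] == 100 and c2["max_epoch"] == 1000
        assert c2["augment_resize"] == 0.05 and c2["augment_shift_px"] == 2

    def test_augmentation_caps_enforced(self):
        with pytest.raises(ValueError, match="caps"):
            TrainConfig(stage=1, augment_resize=0.2).resolved()
        with pytest.raises(ValueError, match="caps"):
            TrainConfig(stage=2, augment_shift_px=5).resolved()

    def test_bad_stage_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(stage=3).resolved()


class TestPatchClassifierTraining:
    def test_separable_toy_reaches_perfect_validation(self):
        X, y = toy_patches()
        clf = PatchClassifier(max_epoch=50, random_state=0)
        clf.fit(X, y)
        assert clf.validation_accuracy_ == 1.0
        assert clf.n_epochs_ <= 50

    def test_label_shuffle_gives_chance_accuracy(self):
        rng = np.random.default_rng(1)
        X, y = toy_patches(n=200, seed=1)
        y = rng.permutation(y)
        clf = PatchClassifier(max_epoch=30, patience=30, random_state=1)
        clf.fit(X, y)
        assert clf.validation_accuracy_ == pytest.approx(0.5, abs=0.12)

    def test_single_class_rejected(self):
        X, _ = toy_patches(n=20)
        with pytest.raises(ValueError, match="single class"):
            PatchClassifier().fit(X, np.zeros(20, dtype=int))

    def test_training_is_deterministic_under_seed(self):
        X, y = toy_patches(n=60)
        a = PatchClassifier(max_epoch=5, random_state=3).fit(X, y)
        b = PatchClassifier(max_epoch=5, random_state=3).fit(X, y)
        np.testing.assert_array_equal(
            a.predict_proba(X), b.predict_proba(X))

    def test_sklearn_param_protocol(self):
        clf = PatchClassifier(mini_batch=10)
        assert clf.get_params()["mini_batch"] == 10
        clf.set_params(lr=5e-3)
        assert clf.lr == 5e-3


class TestPatchSegmenterTraining:
    def test_single_pixel_class_rejected(self):
        X = np.zeros((10, 16, 16))
        Y = np.zeros((10, 16, 16), dtype=int)
        with pytest.raises(ValueError, match="single"):
            PatchSegmenter().fit(X, Y)

    def test_learns_bright_disk_segmentation(self):
        rng = np.random.default_rng(0)
        p = 16
        X = rng.normal(0.3, 0.02, (80, p, p))
        Y = np.zeros((80, p, p), dtype=int)
        gy, gx = np.mgrid[0:p, 0:p]
        for i in range(80):
            cy, cx = rng.integers(4, p - 4, 2)
            disk = (gy - cy) ** 2 + (gx - cx) ** 2 < 9
            X[i][disk] += 0.5
            Y[i][disk] = 1
        seg = PatchSegmenter(mini_batch=20, max_epoch=60, patience=10,
                             random_state=0)
        seg.fit(X, Y)
        assert seg.validation_accuracy_ > 0.95


class TestGradCam:
    def test_linear_toy_network_closed_form(self, rng):
        # conv -> ReLU -> GAP -> dense: the class-score gradient w.r.t. the
        # feature maps is W[:, c]/(HW), so the map is the rectified
        # W-weighted sum of the feature maps (then max-normalized)
        net = Sequential([Conv2D(1, 3, 3, "same", rng), ReLU(),
                          GlobalAvgPool(), Dense(3, 2, rng)])
        X = rng.normal(size=(4, 1, 12, 12)).astype(np.float32)
        maps = grad_cam_from_net(net, X, 1, feature_layer=1,
                                 out_size=(12, 12))
        feats = net.layers[1].forward(net.layers[0].forward(X))
        w = net.layers[-1].w[:, 1] / (12 * 12)
        expected = np.maximum((w[None, :, None, None] * feats).sum(1), 0)
        for i in range(4):
            e = expected[i]
            if e.max() > 0:
                e = e / e.max()
            np.testing.assert_allclose(maps[i], e, atol=1e-5)

    def test_maps_bounded_in_unit_interval(self, trained_bundle, rng):
        patch = rng.uniform(0, 1, (32, 32))
        m = grad_cam(trained_bundle, patch)
        assert m.scores.min() >= 0.0 and m.scores.max() <= 1.0
        assert m.scores.shape == (32, 32)

    def test_class_index_out_of_range(self, trained_bundle, rng):
        with pytest.raises(ValueError, match="class_index"):
            grad_cam(trained_bundle, rng.uniform(0, 1, (32, 32)),
                     class_index=7)

    def test_map_concentrates_on_true_vesicles(self, trained_bundle,
                                               segment_dataset):
        # over >=100 positive patches, mean Grad-CAM score inside the true
        # vesicle mask exceeds the mean outside
        X, Y = segment_dataset.subset("train")
        pos = np.flatnonzero(Y.sum(axis=(1, 2)) > 0)[:120]
        maps = trained_bundle.stage1.grad_cam(X[pos])
        inside, outside = [], []
        for m, y in zip(maps, Y[pos]):
            fg = y.astype(bool)
            inside.append(m.scores[fg].mean())
            outside.append(m.scores[~fg].mean())
        assert np.mean(inside) > np.mean(outside)


class TestTrainStage:
    def test_mode_mismatch_rejected(self, classify_dataset):
        with pytest.raises(ValueError, match="segment"):
            train_stage(classify_dataset, TrainConfig(stage=2))

    def test_bundle_roundtrip_preserves_predictions(self, trained_bundle,
                                                    tmp_path, rng):
        path = tmp_path / "model.bundle"
        trained_bundle.save(path)
        loaded = ModelBundle.load(path)
        X = rng.uniform(0, 1, (8, 32, 32))
        np.testing.assert_array_equal(loaded.stage1.predict_proba(X),
                                      trained_bundle.stage1.predict_proba(X))
        np.testing.assert_array_equal(loaded.stage2.predict_proba(X),
                                      trained_bundle.stage2.predict_proba(X))
        assert loaded.training_report.keys() == \
            trained_bundle.training_report.keys()


class TestScanLocalize:
    def test_blank_image_gives_no_rois(self, trained_bundle):
        blank = PixelImage(np.full((128, 128), 145, dtype=np.uint8), 5.0)
        rois = scan_localize(trained_bundle, blank, roi_threshold=0.5)
        assert rois == []

    def test_single_vesicle_gives_one_roi_containing_it(
            self, trained_bundle, one_vesicle_field):
        img, truth = one_vesicle_field
        rois = scan_localize(trained_bundle, img)
        assert len(rois) == 1
        cx, cy = truth.vesicle_centers[0]
        r = rois[0]
        assert r.x0 <= cx <= r.x1 and r.y0 <= cy <= r.y1

    def test_image_smaller_than_patch_rejected(self, trained_bundle):
        tiny = PixelImage(np.zeros((16, 16), dtype=np.uint8), 5.0)
        with pytest.raises(ValueError, match="smaller"):
            scan_localize(trained_bundle, tiny)

    def test_raising_threshold_never_adds_rois(self, trained_bundle):
        img, _ = synthesize_vesicle_field(density_per_um2=3.0, seed=77)
        det = trained_bundle.detector()
        counts = [len(det.scan_localize(img, roi_threshold=t)[0])
                  for t in (0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_stride_halving_keeps_roi_count_stable(self, trained_bundle):
        img, _ = synthesize_vesicle_field(density_per_um2=2.0, seed=78)
        det = trained_bundle.detector()
        full = len(det.scan_localize(img, stride_px=32)[0])
        half = len(det.scan_localize(img, stride_px=16)[0])
        assert abs(full - half) <= max(1, 0.2 * max(full, half))


class TestSegmentVesicles:
    def test_empty_roi_list_gives_no_instances(self, trained_bundle):
        img, _ = synthesize_vesicle_field(seed=5)
        assert segment_vesicles(trained_bundle, img, []) == []

    def test_well_separated_vesicles_counted_exactly(self, trained_bundle):
        hits = 0
        total = 0
        for seed in range(6):
            img, truth = synthesize_vesicle_field(density_per_um2=2.0,
                                                  seed=300 + seed)
            k = truth.vesicle_count
            if not 1 <= k <= 20:
                continue
            det = trained_bundle.detector().detect(img)
            total += 1
            hits += abs(len(det) - k) <= 1
        assert total >= 3 and hits == total

    def test_recovered_diameters_match_generator(self, trained_bundle):
        diams = []
        for seed in range(5):
            img, _ = synthesize_vesicle_field(density_per_um2=3.0,
                                              seed=400 + seed)
            diams += [v.equivalent_diameter_nm
                      for v in trained_bundle.detector().detect(img)]
        assert len(diams) >= 10
        assert np.mean(diams) == pytest.approx(50.0, abs=10.0)

    def test_reflection_equivariance(self, trained_bundle):
        img, truth = synthesize_vesicle_field(density_per_um2=2.0, seed=91)
        det = trained_bundle.detector()
        orig = det.detect(img)
        mirrored = PixelImage(img.data[:, ::-1].copy(), img.nm_per_px)
        refl = det.detect(mirrored)
        assert len(orig) == len(refl)
        w = img.data.shape[1]
        back = sorted((w - 1 - v.centroid[0], v.centroid[1]) for v in refl)
        fwd = sorted(v.centroid for v in orig)
        for (x1, y1), (x2, y2) in zip(fwd, back):
            assert abs(x1 - x2) <= 2 and abs(y1 - y2) <= 2

    def test_unfitted_detector_raises(self):
        det = VesicleDetector()
        img, _ = synthesize_vesicle_field(seed=1)
        with pytest.raises(ValueError, match="not fitted"):
            det.detect(img)
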