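"""Augmentation, masked Dice loss, schedules, and the estimator contract."""

import numpy as np
import pytest
from sklearn.base import clone

import thalseg as ts
from thalseg.estimators import ThalamicNucleiSegmenter


def _toy_pair(rng, shape=(16, 16, 16)):
    labels = np.zeros(shape, dtype=np.int16)
    labels[4:12, 4:12, 4:12] = rng.integers(1, 14, size=(8, 8, 8))
    labels[7:9, 7:9, 7:9] = 100
    image = rng.random(shape)
    return image, labels


class TestAugment:
    def test_identity_config_is_exact_identity(self, rng):
        image, labels = _toy_pair(rng)
        out_img, out_lab = ts.augment(image, labels, ts.AugmentationConfig.identity(), rng)
        assert np.array_equal(out_img, image)
        assert np.array_equal(out_lab, labels)

    def test_flip_is_involution(self, rng):
        image, labels = _toy_pair(rng)
        cfg = ts.AugmentationConfig.identity()
        cfg = type(cfg)(**{**cfg.__dict__, "flip_prob": 1.0})
        img1, lab1 = ts.augment(image, labels, cfg, rng)
        img2, lab2 = ts.augment(img1, lab1, cfg, rng)
        assert np.array_equal(img2, image)
        assert np.array_equal(lab2, labels)

    def test_zero_log_gamma_leaves_intensity_unchanged(self, rng):
        image, labels = _toy_pair(rng)
        cfg = ts.AugmentationConfig.identity()
        assert cfg.log_gamma_range == (0.0, 0.0)
        out_img, _ = ts.augment(image, labels, cfg, rng)
        assert np.array_equal(out_img, image)

    def test_full_augmentation_keeps_label_values_legal(self, rng):
        image, labels = _toy_pair(rng, shape=(24, 24, 24))
        for _ in range(5):
            out_img, out_lab = ts.augment(image, labels, ts.AugmentationConfig(), rng)
            present = set(np.unique(out_lab).tolist())
            assert present <= (set(range(14)) | {100})
            assert out_img.shape == image.shape

    def test_same_spatial_transform_for_image_and_labels(self, rng):
        # encode the label grid as an image: nearest-neighbor transport of a
        # piecewise-constant volume must agree where interpolation is exact
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        labels[5:15, 5:15, 5:15] = 7
        image = labels.astype(float)
        cfg = ts.AugmentationConfig(
            flip_prob=1.0,
            rot_max_deg=0.0,
            scale_range=(1.0, 1.0),
            translate_max_vox=0.0,
            elastic_max_disp_vox=0.0,
            log_gamma_range=(0.0, 0.0),
        )
        out_img, out_lab = ts.augment(image, labels, cfg, rng)
        assert np.array_equal(out_img.astype(np.int16), out_lab)


class TestMaskedDiceLoss:
    def _probs(self, classes, shape):
        probs = np.zeros((14, *shape))
        for idx, cls in np.ndenumerate(classes):
            probs[(cls,) + idx] = 1.0
        return probs

    def test_worked_four_voxel_case(self):
        labels = np.array([0, 1, 1, 100], dtype=np.int16).reshape(4, 1, 1)
        pred_cls = np.array([0, 1, 0, 5]).reshape(4, 1, 1)
        probs = self._probs(pred_cls, (4, 1, 1))
        loss = ts.masked_dice_loss(probs, labels)
        # class 0 and class 1 each have Dice 2/3; 12 classes score 0
        assert loss == pytest.approx(1 - (4 / 3) / 14, abs=1e-4)

    def test_perfect_prediction_with_all_classes_present(self, rng):
        labels = rng.integers(0, 14, size=(6, 6, 6)).astype(np.int16)
        for c in range(14):
            labels.reshape(-1)[c] = c  # guarantee presence
        probs = self._probs(labels, labels.shape)
        assert ts.masked_dice_loss(probs, labels) < 1e-3

    def test_fully_disjoint_prediction_scores_one(self):
        labels = np.full((4, 4, 4), 3, dtype=np.int16)
        probs = self._probs(np.full((4, 4, 4), 5), labels.shape)
        assert ts.masked_dice_loss(probs, labels) == pytest.approx(1.0, abs=1e-6)

    def test_sentinel_voxels_contribute_exactly_nothing(self, rng):
        _, labels = _toy_pair(rng)
        probs = rng.random((14, *labels.shape))
        probs /= probs.sum(axis=0, keepdims=True)
        base = ts.masked_dice_loss(probs, labels)
        perturbed = probs.copy()
        perturbed[:, labels == 100] = rng.random((14, int((labels == 100).sum())))
        assert ts.masked_dice_loss(perturbed, labels) == base  # bitwise

    def test_loss_bounds_on_random_inputs(self, rng):
        for _ in range(20):
            _, labels = _toy_pair(rng)
            probs = rng.random((14, *labels.shape))
            probs /= probs.sum(axis=0, keepdims=True)
            loss = ts.masked_dice_loss(probs, labels)
            assert 0.0 <= loss <= 1.0

    def test_no_labeled_voxels_rejected(self):
        labels = np.full((3, 3, 3), 100, dtype=np.int16)
        with pytest.raises(ts.UsageError):
            ts.masked_dice_loss(np.full((14, 3, 3, 3), 1 / 14), labels)

    def test_gradient_matches_finite_differences(self, rng):
        labels = rng.integers(0, 14, size=(4, 4, 4)).astype(np.int16)
        labels[0, 0, :2] = 100
        probs = rng.random((14, 4, 4, 4))
        probs /= probs.sum(axis=0, keepdims=True)
        loss, grad = ts.masked_dice_loss_and_grad(probs, labels)
        assert loss == pytest.approx(ts.masked_dice_loss(probs, labels))
        eps = 1e-7
        for (c, i, j, k) in [(0, 1, 1, 1), (5, 2, 3, 0), (13, 0, 0, 0), (3, 0, 0, 1)]:
            p = probs.copy()
            p[c, i, j, k] += eps
            fd = (ts.masked_dice_loss(p, labels) - loss) / eps
            assert grad[c, i, j, k] == pytest.approx(fd, rel=1e-4, abs=1e-9)
        assert np.all(grad[:, labels == 100] == 0.0)

    def test_ignore_absent_option(self):
        labels = np.full((4, 4, 4), 3, dtype=np.int16)
        probs = self._probs(np.full((4, 4, 4), 3), labels.shape)
        strict = ts.masked_dice_loss(probs, labels)
        lenient = ts.masked_dice_loss(
            probs, labels, ts.LossConfig(ignore_absent=True)
        )
        assert strict == pytest.approx(13 / 14, abs=1e-4)  # 13 absent classes
        assert lenient < 1e-3


def _micro_fit(rng, mode="full", max_epochs=3, **kwargs):
    image, labels = _toy_pair(rng)
    est = ThalamicNucleiSegmenter(
        levels=2,
        base_width=2,
        mode=mode,
        max_epochs=max_epochs,
        crop_size=16,
        augmentation=ts.AugmentationConfig.identity(),
        seed=11,
        **kwargs,
    )
    val = ([image], [labels]) if mode == "crossval" else None
    est.fit([image], [labels], validation=val)
    return est


class TestTrainingSchedules:
    def test_full_mode_records_requested_epochs(self, rng):
        est = _micro_fit(rng, max_epochs=3, decay_every=1000)
        assert [rec["epoch"] for rec in est.history_] == [1, 2, 3]
        assert all(rec["lr"] == pytest.approx(1e-3) for rec in est.history_)

    def test_full_mode_lr_decays_ten_percent_every_ten_epochs(self, rng):
        est = _micro_fit(rng, max_epochs=21)
        lrs = [rec["lr"] for rec in est.history_]
        # record holds the lr used during the epoch
        assert lrs[9] == pytest.approx(1e-3)
        assert lrs[10] == pytest.approx(0.9e-3)
        assert lrs[20] == pytest.approx(0.81e-3)

    def test_seeded_determinism(self, rng):
        h1 = _micro_fit(rng, max_epochs=3).history_
        h2 = _micro_fit(np.random.default_rng(7), max_epochs=3).history_
        assert h1 == h2

    def test_crossval_requires_validation(self, rng):
        image, labels = _toy_pair(rng)
        est = ThalamicNucleiSegmenter(mode="crossval", levels=2, base_width=2)
        with pytest.raises(ts.UsageError):
            est.fit([image], [labels])

    def test_crossval_mode_tracks_validation_loss(self, rng):
        est = _micro_fit(rng, mode="crossval", max_epochs=3)
        assert all(rec["val_loss"] is not None for rec in est.history_)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ts.UsageError):
            ts.TrainSchedule(mode="warm-restart")


def test_train_model_wrapper_returns_fitted_estimator(rng):
    image, labels = _toy_pair(rng)
    from thalseg.model import NetworkConfig

    est = ts.train_model(
        [(image, labels)],
        net_cfg=NetworkConfig(levels=2, base_width=2),
        sched=ts.TrainSchedule(mode="full", max_epochs=2, crop_size=16, seed=4),
        aug=ts.AugmentationConfig.identity(),
    )
    assert len(est.history_) == 2
    (seg,) = est.predict([image])
    assert seg.shape == image.shape


class TestEstimatorContract:
    def test_get_set_params_and_clone(self):
        est = ThalamicNucleiSegmenter(base_width=8, crop_size=32)
        params = est.get_params()
        assert params["base_width"] == 8
        est2 = clone(est)
        assert est2.get_params() == params
        est2.set_params(base_width=4)
        assert est2.base_width == 4 and est.base_width == 8

    def test_predict_before_fit_rejected(self, rng):
        with pytest.raises(ts.UsageError):
            ThalamicNucleiSegmenter().predict([rng.random((16, 16, 16))])

    def test_predict_pads_back_to_original_extent(self, rng):
        est = _micro_fit(rng)
        image = rng.random((24, 20, 18))
        (seg,) = est.predict([image])
        assert seg.shape == image.shape
        # voxels outside the central 16^3 crop are background
        border = seg.copy()
        border[4:20, 2:18, 1:17] = 0
        assert np.all(border == 0)

    def test_training_reduces_loss(self, rng):
        est = _micro_fit(rng, max_epochs=30)
        losses = [rec["train_loss"] for rec in est.history_]
        assert losses[-1] < losses[0]
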