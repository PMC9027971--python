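import math
import warnings

import numpy as np
import pytest

from kneeplan.decoding import FeatureSet
from kneeplan.geometry import Keypoint, Polyline
from kneeplan.model import TaskKind, TaskSpec
from kneeplan.training import (
    AugmentParams,
    TaskWeights,
    TrainConfig,
    augment,
    clr_schedule,
    composite_loss,
    geometric_preprocess,
    gradnorm_step,
    normalize_intensity,
    task_loss,
    task_loss_and_grad,
)


class TestNormalization:
    def test_min_max_formula(self):
        out = normalize_intensity(np.array([0.0, 127.5, 255.0]))
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_already_unit_range_unchanged(self):
        img = np.array([[0.0, 0.25], [0.75, 1.0]])
        assert np.allclose(normalize_intensity(img), img)

    def test_constant_image_guard(self):
        with pytest.warns(UserWarning):
            out = normalize_intensity(np.full((4, 4), 3.0))
        assert np.all(out == 0.0)


class TestGeometricPreprocess:
    def test_downscale_and_pad(self):
        img = np.ones((512, 384))
        fs = FeatureSet()
        fs.add(Keypoint(100.0, 100.0, label="K1"))
        out, mapped, fmap = geometric_preprocess(img, fs, target=256)
        assert out.shape == (256, 256)
        assert fmap.scale == pytest.approx(0.5)
        # content occupies 256 x 192, right side zero-padded
        assert np.all(out[:, 192:] == 0.0)
        assert np.any(out[:, :192] > 0.0)
        kp = mapped.keypoints["K1"]
        assert (kp.x, kp.y) == (50.0, 50.0)

    def test_identity_for_target_size(self):
        img = np.random.default_rng(0).random((256, 256))
        out, _, fmap = geometric_preprocess(img, None, target=256)
        assert np.array_equal(out, img)
        assert fmap.scale == 1.0

    def test_round_trip_exact(self):
        _, _, fmap = geometric_preprocess(np.zeros((300, 200)), None, target=256)
        p = np.array([[12.3, 45.6]])
        assert np.allclose(fmap.inverse(fmap.forward(p)), p, atol=1e-9)


class TestAugmentation:
    def test_horizontal_flip_formula(self, rng):
        fs = FeatureSet()
        fs.add(Keypoint(30.0, 40.0, label="K1"))
        params = AugmentParams(flip=True)
        _, out = augment(np.zeros((256, 256)), fs, rng, params=params)
        kp = out.keypoints["K1"]
        assert kp.x == pytest.approx(255.0 - 30.0)
        assert kp.y == pytest.approx(40.0)

    def test_identity_draw_is_noop(self, rng):
        img = np.random.default_rng(1).random((64, 64))
        fs = FeatureSet()
        fs.add(Polyline(points=np.array([[5.0, 5.0], [20.0, 30.0]]), label="L1"))
        out_img, out_fs = augment(img, fs, rng, params=AugmentParams())
        assert np.allclose(out_img, img, atol=1e-9)
        assert np.allclose(out_fs.lines["L1"].points, fs.lines["L1"].points, atol=1e-9)

    def test_rotation_inverse_composition(self, rng):
        fs = FeatureSet()
        fs.add(Keypoint(100.0, 60.0, label="K1"))
        img = np.zeros((256, 256))
        _, fwd = augment(img, fs, rng, params=AugmentParams(rotation_deg=45.0))
        _, back = augment(img, fwd, rng, params=AugmentParams(rotation_deg=-45.0))
        kp = back.keypoints["K1"]
        assert kp.x == pytest.approx(100.0, abs=1e-6)
        assert kp.y == pytest.approx(60.0, abs=1e-6)


class TestLosses:
    def _seg_task(self, c=1):
        return TaskSpec(name="seg", kind=TaskKind.segmentation, n_channels=c)

    def _hm_task(self):
        return TaskSpec(name="kpt", kind=TaskKind.keypoint, n_channels=1)

    def test_mse_zero_on_identity(self):
        t = np.random.default_rng(0).random((1, 16, 16))
        assert task_loss(self._hm_task(), t, t) == 0.0

    def test_mse_of_zero_prediction_equals_mean_square_target(self):
        t = np.random.default_rng(1).random((2, 16, 16))
        assert task_loss(self._hm_task(), np.zeros_like(t), t) == pytest.approx(
            float(np.mean(t * t))
        )

    def test_perfect_segmentation_near_zero(self):
        t = np.zeros((1, 32, 32))
        t[0, 5:20, 5:20] = 1.0
        p = np.clip(t, 1e-6, 1 - 1e-6)
        assert task_loss(self._seg_task(), p, t) <= 1e-3

    def test_uniform_half_vs_ones_closed_form(self):
        # BCE = ln 2; soft-Dice term = 1 - (2*0.5)/(0.5+1) = 1/3 (up to eps smoothing)
        t = np.ones((1, 64, 64))
        p = np.full((1, 64, 64), 0.5)
        expected = math.log(2.0) + 1.0 / 3.0
        assert task_loss(self._seg_task(), p, t) == pytest.approx(expected, abs=2e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            task_loss(self._hm_task(), np.zeros((1, 8, 8)), np.zeros((1, 9, 9)))

    @pytest.mark.parametrize("kind", [TaskKind.keypoint, TaskKind.segmentation])
    def test_gradient_matches_finite_differences(self, kind, rng):
        task = TaskSpec(name="t", kind=kind, n_channels=2)
        p = rng.uniform(0.2, 0.8, size=(2, 6, 6))
        t = (rng.random((2, 6, 6)) > 0.5).astype(float) if kind == TaskKind.segmentation else rng.random((2, 6, 6))
        loss, grad = task_loss_and_grad(task, p, t)
        eps = 1e-6
        for idx in [(0, 1, 2), (1, 3, 4), (0, 5, 5)]:
            pp = p.copy()
            pp[idx] += eps
            num = (task_loss(task, pp, t) - loss) / eps
            assert grad[0][idx] == pytest.approx(num, rel=1e-3, abs=1e-8)

    def test_composite_loss(self):
        w = TaskWeights.uniform(["a", "b", "c"])
        assert composite_loss({"a": 1.0, "b": 2.0, "c": 3.0}, w) == 6.0
        w2 = TaskWeights(w={"a": 2.0, "b": 0.5})
        assert composite_loss({"a": 1.0, "b": 2.0}, w2) == 3.0
        with pytest.raises(KeyError):
            composite_loss({"a": 1.0, "z": 2.0}, w2)


class TestSchedule:
    def test_printed_anchor_points(self):
        cfg = TrainConfig()
        assert clr_schedule(0, cfg) == (pytest.approx(0.001), pytest.approx(0.9))
        assert clr_schedule(180, cfg) == (pytest.approx(0.1), pytest.approx(0.8))
        assert clr_schedule(360, cfg) == (pytest.approx(0.001), pytest.approx(0.9))

    def test_midpoint_interpolation(self):
        lr, mom = clr_schedule(90, TrainConfig())
        assert lr == pytest.approx(0.001 + 0.5 * (0.1 - 0.001))
        assert mom == pytest.approx(0.9 - 0.5 * (0.9 - 0.8))

    def test_periodicity(self):
        cfg = TrainConfig()
        for it in (7, 133, 299):
            assert clr_schedule(it, cfg) == clr_schedule(it + 360, cfg)


class TestGradNorm:
    def test_sum_preserved_and_positive(self, rng):
        w = TaskWeights.uniform(["a", "b", "c"])
        for step in range(50):
            losses = {k: float(rng.uniform(0.1, 2.0)) for k in "abc"}
            init = {k: 1.0 for k in "abc"}
            norms = {k: float(rng.uniform(0.01, 1.0)) for k in "abc"}
            w = gradnorm_step(w, losses, init, norms)
            assert sum(w.w.values()) == pytest.approx(3.0)
            assert all(v > 0 for v in w.w.values())

    def test_single_task_degenerates(self):
        w = TaskWeights.uniform(["only"])
        out = gradnorm_step(w, {"only": 0.5}, {"only": 1.0}, {"only": 0.3})
        assert out.w["only"] == pytest.approx(1.0)

    def test_identical_tasks_stay_equal(self):
        w = TaskWeights.uniform(["a", "b"])
        for _ in range(100):
            w = gradnorm_step(w, {"a": 0.7, "b": 0.7}, {"a": 1.0, "b": 1.0}, {"a": 0.4 * w.w["a"], "b": 0.4 * w.w["b"]})
        assert w.w["a"] == pytest.approx(w.w["b"], abs=1e-9)

    def test_nonfinite_norms_skip_update(self):
        w = TaskWeights(w={"a": 1.5, "b": 0.5})
        with pytest.warns(UserWarning):
            out = gradnorm_step(w, {"a": 1.0, "b": 1.0}, {"a": 1.0, "b": 1.0}, {"a": float("nan"), "b": 1.0})
        assert out.w == w.w
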