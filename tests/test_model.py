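import numpy as np
import pytest

from kneeplan.model import ModelConfig, TaskKind, TaskSpec, Topology, build_model

TASKS = (
    TaskSpec(name="seg", kind=TaskKind.segmentation, n_channels=2),
    TaskSpec(name="kpt", kind=TaskKind.keypoint, n_channels=3),
    TaskSpec(name="lin", kind=TaskKind.line, n_channels=1),
)


def small_config(topology, **kw):
    defaults = dict(tasks=TASKS, n_features=8, depth=2, input_size=32, seed=0)
    defaults.update(kw)
    return ModelConfig(topology=topology, **defaults)


class TestConstruction:
    def test_parameter_count_ordering(self):
        n_mh = build_model(small_config("multi_head")).n_params()
        n_md = build_model(small_config("multi_decoder")).n_params()
        n_st = build_model(small_config("single_task")).n_params()
        assert n_mh < n_md < n_st

    def test_output_channels_per_task(self):
        model = build_model(small_config("multi_head"))
        outs = model.forward(np.zeros((1, 1, 32, 32)))
        assert set(outs) == {"seg", "kpt", "lin"}
        for task in TASKS:
            assert outs[task.name].shape == (1, task.n_channels, 32, 32)

    def test_invalid_topology_rejected(self):
        with pytest.raises(ValueError):
            small_config("u_net")

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(tasks=TASKS, topology="multi_head", depth=4, input_size=250)

    def test_duplicate_task_names_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(tasks=(TASKS[0], TASKS[0]), topology="multi_head", input_size=32, depth=2)


class TestInference:
    def test_segmentation_squashed_heatmap_raw(self):
        model = build_model(small_config("multi_head"))
        outs = model.infer(np.random.default_rng(0).random((32, 32)))
        assert np.all((outs["seg"] >= 0) & (outs["seg"] <= 1))
        for name, out in outs.items():
            assert out.shape[1:] == (32, 32)

    def test_wrong_input_size_rejected(self):
        model = build_model(small_config("multi_head"))
        with pytest.raises(ValueError):
            model.infer(np.zeros((31, 31)))

    def test_deterministic_outputs(self):
        x = np.random.default_rng(3).random((32, 32))
        a = build_model(small_config("multi_head")).infer(x)
        b = build_model(small_config("multi_head")).infer(x)
        for k in a:
            assert np.array_equal(a[k], b[k])


class TestParameterSharing:
    @pytest.mark.parametrize("topology", ["multi_head", "multi_decoder"])
    def test_shared_weight_affects_all_tasks(self, topology):
        model = build_model(small_config(topology))
        x = np.random.default_rng(0).random((32, 32))
        base = model.infer(x)
        model.encoders[0].stem.W.data += 0.05
        perturbed = model.infer(x)
        for k in base:
            assert not np.allclose(base[k], perturbed[k])

    @pytest.mark.parametrize("topology", ["multi_head", "multi_decoder", "single_task"])
    def test_head_weight_affects_only_its_task(self, topology):
        model = build_model(small_config(topology))
        x = np.random.default_rng(0).random((32, 32))
        base = model.infer(x)
        model.heads[1].conv.W.data += 0.05  # the "kpt" head
        perturbed = model.infer(x)
        assert not np.allclose(base["kpt"], perturbed["kpt"])
        assert np.allclose(base["seg"], perturbed["seg"])
        assert np.allclose(base["lin"], perturbed["lin"])


class TestGradients:
    @pytest.mark.parametrize("topology", ["multi_head", "multi_decoder"])
    def test_backward_matches_finite_differences(self, topology, rng):
        """End-to-end gradient check of the hand-written backpropagation."""
        model = build_model(small_config(topology, n_features=4, depth=1, input_size=8))
        model.set_train(True)
        x = rng.random((2, 1, 8, 8))
        targets = {t.name: rng.random((2, t.n_channels, 8, 8)) for t in TASKS}

        def total_loss():
            outs = model.forward(x)
            return sum(float(np.mean((outs[k] - targets[k]) ** 2)) for k in targets)

        outs = model.forward(x)
        model.zero_grad()
        d_outs = {k: 2.0 * (outs[k] - targets[k]) / outs[k].size for k in targets}
        model.backward(d_outs)
        params = list(model.parameters())
        base = total_loss()
        check = [params[0], params[len(params) // 2], params[-1]]
        for p in check:
            flat_idx = p.data.size // 2
            idx = np.unravel_index(flat_idx, p.data.shape)
            eps = 1e-6
            old = p.data[idx]
            p.data[idx] = old + eps
            num = (total_loss() - base) / eps
            p.data[idx] = old
            assert p.grad[idx] == pytest.approx(num, rel=5e-2, abs=1e-7)

    def test_gradnorm_norms_sum_to_full_gradient(self, rng):
        """Per-task shared-layer gradients must add up to the joint gradient."""
        model = build_model(small_config("multi_head", n_features=4, depth=1, input_size=8))
        model.set_train(True)
        x = rng.random((1, 1, 8, 8))
        outs = model.forward(x)
        d_outs = {k: rng.random(v.shape) * 1e-3 for k, v in outs.items()}
        model.zero_grad()
        model.backward(d_outs, collect_gradnorm=True)
        joint = model.tails[0].conv.W.grad.copy()
        model.forward(x)
        model.zero_grad()
        pieces = []
        for name in d_outs:
            model.zero_grad()
            model.forward(x)
            model.backward({k: (v if k == name else np.zeros_like(v)) for k, v in d_outs.items()})
            pieces.append(model.tails[0].conv.W.grad.copy())
        assert np.allclose(sum(pieces), joint, atol=1e-10)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = build_model(small_config("multi_head"))
        x = np.random.default_rng(1).random((32, 32))
        expected = model.infer(x)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        restored = type(model).load(path)
        actual = restored.infer(x)
        for k in expected:
            assert np.array_equal(expected[k], actual[k])
        assert restored.config == model.config
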