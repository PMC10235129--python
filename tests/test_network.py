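"""Architecture contracts, loss functions and gradient correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import echophase as ep
from echophase.errors import ConfigError, DomainError
from echophase.network import (LabeledBatch, LossConfig, ModelConfig,
                               _MaxPool2D, loss_and_grad)


# ---------------------------------------------------------------------------
# independent per-element oracles


def _mse_oracle(t, p):
    total, count = 0.0, 0
    for a, b in zip(np.ravel(t), np.ravel(p)):
        total += (a - b) ** 2
        count += 1
    return total / count


def _mean_oracle(t, p):
    total, count = 0.0, 0
    for a, b in zip(np.ravel(t), np.ravel(p)):
        total += a - b
        count += 1
    return total / count


def _random_batches(n_batches, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_batches):
        n = int(rng.integers(1, 9))
        if rng.random() < 0.5:
            t = rng.integers(0, 2, n).astype(float)
            p = rng.random(n)
        else:  # one-hot 3-class rows
            t = np.eye(3)[rng.integers(0, 3, n)]
            p = rng.random((n, 3))
        yield t, p


class TestLossValues:
    @pytest.mark.parametrize("t,p,expected", [
        ([1, 0], [1, 0], 0.0),
        ([1, 0], [0, 1], 1.0),
        ([1], [0.5], 0.25),
    ])
    def test_mse_hand_values(self, t, p, expected):
        assert ep.mse(np.array(t, float), np.array(p, float)) == pytest.approx(expected)

    @pytest.mark.parametrize("t,p,expected", [
        ([1, 0], [0, 1], 0.0),
        ([1, 1], [0, 0], 1.0),
        ([1, 0, 1], [1, 0, 1], 0.0),
    ])
    def test_mean_error_hand_values(self, t, p, expected):
        assert ep.mean_error(np.array(t, float), np.array(p, float)) == pytest.approx(expected)

    def test_custom_loss_perfect_prediction_is_zero(self):
        t = np.array([1.0, 0.0, 1.0])
        assert ep.custom_loss(t, t, beta=0.7) == 0.0

    def test_custom_loss_hand_value(self):
        t, p = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        assert ep.custom_loss(t, p, beta=0.1) == pytest.approx(1.1)

    def test_custom_loss_small_beta_limit_equals_mse(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, 20).astype(float)
        p = rng.random(20)
        assert ep.custom_loss(t, p, beta=1e-15) == pytest.approx(ep.mse(t, p), abs=1e-12)

    def test_custom_loss_can_go_negative_on_overprediction(self):
        # signed mean term as defined: over-predicting every label makes
        # the regulariser negative
        t = np.array([0.0, 0.0])
        p = np.array([0.9, 0.9])
        assert ep.custom_loss(t, p, beta=2.0) < 0.0

    def test_mae_hand_value(self):
        assert ep.baseline_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5]),
                                kind="mae") == pytest.approx(0.5)

    def test_cross_entropy_near_zero_at_perfect(self):
        t = np.array([1.0, 0.0])
        assert ep.baseline_loss(t, t, kind="cross_entropy") < 1e-5

    def test_baseline_mse_equals_mse_op(self):
        for t, p in _random_batches(100, seed=2):
            assert ep.baseline_loss(t, p, kind="mse") == ep.mse(t, p)

    def test_matches_bruteforce_oracles(self):
        for t, p in _random_batches(300, seed=3):
            assert ep.mse(t, p) == pytest.approx(_mse_oracle(t, p), rel=1e-10)
            assert ep.mean_error(t, p) == pytest.approx(_mean_oracle(t, p),
                                                        rel=1e-10, abs=1e-12)
            beta = 0.3
            assert ep.custom_loss(t, p, beta=beta) == pytest.approx(
                _mse_oracle(t, p) + beta * _mean_oracle(t, p), rel=1e-10, abs=1e-12)

    def test_beta_validation(self):
        t = np.array([1.0])
        with pytest.raises(ConfigError):
            ep.custom_loss(t, t, beta=0.0)
        with pytest.raises(ConfigError):
            LossConfig(kind="custom", beta=0.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(DomainError):
            ep.mse(np.array([]), np.array([]))

    def test_predictions_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            LabeledBatch(np.array([1.0]), np.array([1.5]))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8),
           st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_mean_error_antisymmetric(self, a, b):
        n = min(len(a), len(b))
        x, y = np.array(a[:n]), np.array(b[:n])
        assert ep.mean_error(x, y) == pytest.approx(-ep.mean_error(y, x))


class TestLossGradients:
    def test_custom_gradient_closed_form(self):
        """d/dp [mse + beta*mean] = -2(t-p)/n - beta/n per element."""
        rng = np.random.default_rng(5)
        t = rng.integers(0, 2, 12).astype(float)[:, None]
        p = rng.random((12, 1))
        cfg = LossConfig(kind="custom", beta=0.25)
        _, grad = loss_and_grad(cfg, t, p)
        expected = (-2 * (t - p) - 0.25) / t.size
        assert np.allclose(grad, expected, rtol=1e-12)

    @pytest.mark.parametrize("kind,beta", [("custom", 0.1), ("custom", 0.4),
                                           ("mse", 0.1), ("cross_entropy", 0.1)])
    def test_gradient_matches_finite_differences(self, kind, beta):
        rng = np.random.default_rng(7)
        t = rng.integers(0, 2, 10).astype(float)[:, None]
        p = rng.uniform(0.05, 0.95, (10, 1))
        cfg = LossConfig(kind=kind, beta=beta)
        _, grad = loss_and_grad(cfg, t, p)
        eps = 1e-7
        for i in range(10):
            dp = np.zeros_like(p)
            dp[i, 0] = eps
            num = (loss_and_grad(cfg, t, p + dp)[0]
                   - loss_and_grad(cfg, t, p - dp)[0]) / (2 * eps)
            assert num == pytest.approx(grad[i, 0], rel=1e-5, abs=1e-9)


class TestArchitecture:
    def test_nine_named_layers(self, tiny_model_cfg):
        model = ep.build_model(tiny_model_cfg)
        assert len(model.layer_names) == 9
        assert model.layer_names == ("input", "conv1", "pool1", "conv2",
                                     "pool2", "conv3", "pool3", "dense",
                                     "output")

    def test_default_spatial_trace(self):
        cfg = ModelConfig()
        assert cfg.spatial_trace() == [(148, 148), (74, 74), (72, 72),
                                       (36, 36), (34, 34), (17, 17)]

    def test_pooling_discards_three_quarters(self, rng):
        pool = _MaxPool2D("p", (2, 2))
        x = rng.standard_normal((1, 74, 74, 4)).astype(np.float32)
        out = pool.forward(x, False)
        assert out.shape == (1, 37, 37, 4)
        assert out.size / x.size == 0.25

    def test_parameter_count_regression(self, tiny_model_cfg):
        # independent arithmetic: conv (9*c_in+1)*f, dense (in+1)*out
        model = ep.build_model(tiny_model_cfg)
        expected = ((9 * 1 + 1) * 2 + (9 * 2 + 1) * 3 + (9 * 3 + 1) * 4
                    + (1 * 1 * 4 + 1) * 5 + (5 + 1) * 1)
        assert model.n_parameters() == expected
        assert ep.build_model(ModelConfig()).n_parameters() == 4_827_905

    def test_forward_outputs_probabilities(self, tiny_model_cfg3, rng):
        model = ep.build_model(tiny_model_cfg3, seed=1)
        x = rng.random((5, 22, 22, 1), dtype=np.float32)
        p = model.forward(x)
        assert p.shape == (5, 3)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_seeded_build_reproducible(self, tiny_model_cfg, rng):
        a = ep.build_model(tiny_model_cfg, seed=9)
        b = ep.build_model(tiny_model_cfg, seed=9)
        x = rng.random((3, 22, 22, 1), dtype=np.float32)
        assert np.array_equal(a.forward(x), b.forward(x))

    def test_invalid_n_classes(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_classes=4)

    def test_input_too_small(self):
        with pytest.raises(ConfigError):
            ModelConfig(input_shape=(12, 12, 1))


class TestNetworkGradients:
    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_backprop_matches_finite_differences(self, n_classes):
        """Analytic weight gradients through conv/pool/dense/activation
        match central finite differences on a tiny float64 model."""
        cfg = ModelConfig(input_shape=(22, 22, 1), conv_filters=(2, 3, 4),
                          dense_width=5, n_classes=n_classes)
        model = ep.build_model(cfg, seed=3)
        for layer in model._stack:
            for k, arr in layer.params().items():
                setattr(layer, k, arr.astype(np.float64))
        model.conv1.need_input_grad = True
        rng = np.random.default_rng(0)
        x = rng.random((4, 22, 22, 1))
        y = rng.integers(0, n_classes, 4)
        t = (np.eye(n_classes)[y] if n_classes == 3
             else y.astype(float)[:, None])
        lcfg = LossConfig(kind="custom", beta=0.1)

        def total_loss():
            return loss_and_grad(lcfg, t, model.forward(x).astype(np.float64))[0]

        probs = model.forward(x, train=True)
        _, dp = loss_and_grad(lcfg, t, probs)
        model.backward(dp)
        grads = {(ln, k): g.copy() for ln, k, g in model.gradients()}
        for layer in model._stack:
            for k in layer.params():
                flat = layer.params()[k].ravel()
                g = grads[(layer.name, k)].ravel()
                for i in rng.choice(flat.size, size=min(4, flat.size),
                                    replace=False):
                    eps, old = 1e-6, flat[i]
                    flat[i] = old + eps
                    lp = total_loss()
                    flat[i] = old - eps
                    lm = total_loss()
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    assert num == pytest.approx(g[i], rel=1e-4, abs=1e-8)


class TestWeights:
    def test_average_abs_weight_zero_model(self, tiny_model_cfg):
        model = ep.build_model(tiny_model_cfg)
        for layer in model._stack:
            for k, arr in layer.params().items():
                setattr(layer, k, np.zeros_like(arr))
        assert ep.average_abs_weight(model) == 0.0

    def test_average_abs_weight_plus_minus_one(self, tiny_model_cfg):
        model = ep.build_model(tiny_model_cfg)
        rng = np.random.default_rng(0)
        for layer in model._stack:
            for k, arr in layer.params().items():
                setattr(layer, k, rng.choice([-1.0, 1.0], arr.shape))
        assert ep.average_abs_weight(model) == pytest.approx(1.0)

    def test_matches_bruteforce_flatten(self, tiny_model_cfg):
        model = ep.build_model(tiny_model_cfg, seed=4)
        flat = np.concatenate([arr.ravel()
                               for _, _, arr in model.parameters()])
        assert ep.average_abs_weight(model) == pytest.approx(
            np.abs(flat).mean(), rel=1e-6)

    def test_save_load_round_trip(self, tiny_model_cfg, rng, tmp_path):
        model = ep.build_model(tiny_model_cfg, seed=2)
        path = tmp_path / "weights.npz"
        ep.save_model(model, path)
        back = ep.load_model(path)
        x = rng.random((3, 22, 22, 1), dtype=np.float32)
        assert np.array_equal(model.forward(x), back.forward(x))
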