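import numpy as np
import pytest

import paiq.nn.engine as engine
from paiq.nn import (
    EffNetIQASpec,
    IQDCNNSpec,
    PAQNetSpec,
    TrainConfig,
    build_model,
    evaluate,
    gradcam,
    train,
)
from paiq.nn.engine import (
    Adam,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2x2,
    MBConv,
    ReLU,
    Sequential,
    mae_loss,
)
from paiq.nn.models import _RegressorNet
from paiq.nn.training import LabelScaler


TINY = PAQNetSpec(filters=(4, 8, 8, 8), kernels=(5, 3, 3, 3), dense_units=16,
                  input_size=32)


class TestArchitectures:
    def test_paqnet_parameter_count_is_exactly_2_5m(self):
        model = build_model(PAQNetSpec(), n_outputs=1)
        assert model.n_parameters() == 2_502_273

    def test_paqnet_multi_output_delta(self):
        base = build_model(PAQNetSpec(), n_outputs=1).n_parameters()
        multi = build_model(PAQNetSpec(), n_outputs=5).n_parameters()
        assert multi - base == 4 * 129  # four extra 128->1 heads

    def test_forward_shapes(self):
        x = np.random.default_rng(0).random((2, 128, 128, 1), dtype=np.float32)
        for spec, n_out in ((PAQNetSpec(), 1), (IQDCNNSpec(), 2), (EffNetIQASpec(), 5)):
            model = build_model(spec, n_outputs=n_out)
            assert model.forward(x).shape == (2, n_out)

    def test_effnet_single_channel_input_and_size(self):
        model = build_model(EffNetIQASpec(), n_outputs=1)
        assert 3.5e6 < model.n_parameters() < 4.5e6  # ~4.2 M, B0-sized

    def test_zero_weights_give_zero_output(self):
        model = build_model(TINY, n_outputs=1)
        state = model.state_dict()
        model.load_state_dict({k: np.zeros_like(v) for k, v in state.items()})
        x = np.random.default_rng(0).random((3, 32, 32, 1), dtype=np.float32)
        assert np.allclose(model.forward(x), 0.0)

    def test_invalid_n_outputs(self):
        with pytest.raises(ValueError):
            build_model(PAQNetSpec(), n_outputs=0)


class TestEngineGradients:
    def test_backprop_matches_finite_differences(self, monkeypatch):
        """Analytic gradients agree with central differences (float64 probe)."""
        monkeypatch.setattr(engine, "F32", np.float64)
        rng = np.random.default_rng(3)
        net = Sequential(
            Conv2d(1, 6, 3, padding=1, bias=False, rng=rng), BatchNorm2d(6),
            ReLU(), MaxPool2x2(),
            MBConv(6, 8, 3, 2, 6, rng=rng),
            Conv2d(8, 4, 3, stride=2, padding=1, rng=rng), ReLU(),
            GlobalAvgPool(), Linear(4, 2, rng=rng),
        )
        x = rng.random((2, 16, 16, 1)) - 0.25
        probe = rng.random((2, 2))

        def loss():
            return float((net.forward(x, training=True) * probe).sum())

        net.zero_grad()
        net.forward(x, training=True)
        net.backward(probe.copy())
        checked = 0
        for _, mod, name, param in net.named_parameters():
            flat = param.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, old = 1e-6, flat[idx]
                flat[idx] = old + eps
                up = loss()
                flat[idx] = old - eps
                down = loss()
                flat[idx] = old
                numeric = (up - down) / (2 * eps)
                analytic = float(mod.grads[name].ravel()[idx])
                if abs(numeric) + abs(analytic) > 1e-4:
                    assert numeric == pytest.approx(analytic, rel=1e-4)
                    checked += 1
        assert checked > 20

    def test_adam_descends_quadratic(self):
        lin = Linear(4, 1, rng=np.random.default_rng(0))
        opt = Adam(lin, lr=5e-2)
        x = np.random.default_rng(1).random((64, 4)).astype(np.float32)
        target = (x @ np.array([1.0, -2.0, 0.5, 3.0]))[:, None].astype(np.float32)
        first = None
        for _ in range(300):
            lin.zero_grad()
            loss, grad = mae_loss(lin.forward(x), target)
            first = first if first is not None else loss
            lin.backward(grad)
            opt.step()
        assert loss < 0.2 * first


class TestTraining:
    def _toy_data(self, rng, n=96):
        X = rng.random((n, 32, 32, 1), dtype=np.float32)
        y = X.mean(axis=(1, 2, 3), keepdims=False)[:, None].astype(np.float64)
        return X, y

    def test_loss_decreases(self, rng):
        X, y = self._toy_data(rng)
        model = build_model(TINY, n_outputs=1, seed=0)
        _, hist = train(model, X[:64], y[:64], X[64:], y[64:],
                        TrainConfig(max_epochs=5, learning_rate=1e-3, seed=0))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_constant_labels_learned(self, rng):
        X = rng.random((80, 32, 32, 1), dtype=np.float32)
        y = np.full((80, 1), 0.37)
        model = build_model(TINY, n_outputs=1, seed=0)
        model, hist = train(model, X[:64], y[:64], X[64:], y[64:],
                            TrainConfig(max_epochs=40, learning_rate=1e-2, seed=0))
        assert min(hist["val_loss"]) < 0.02

    def test_patience_zero_stops_after_first_regression(self, rng):
        X, y = self._toy_data(rng, n=48)
        model = build_model(TINY, n_outputs=1, seed=0)
        # huge lr makes validation loss bounce, triggering the stop early
        _, hist = train(model, X[:32], y[:32], X[32:], y[32:],
                        TrainConfig(max_epochs=50, learning_rate=0.5,
                                    patience=0, seed=0))
        assert len(hist["val_loss"]) < 50
        worsened = [i for i in range(1, len(hist["val_loss"]))
                    if hist["val_loss"][i] >= hist["val_loss"][i - 1]]
        assert worsened and len(hist["val_loss"]) == worsened[0] + 1

    def test_reproducible_history(self, rng):
        X, y = self._toy_data(rng, n=48)
        h = []
        for _ in range(2):
            model = build_model(TINY, n_outputs=1, seed=3)
            _, hist = train(model, X[:32], y[:32], X[32:], y[32:],
                            TrainConfig(max_epochs=3, seed=3))
            h.append(hist["train_loss"])
        assert h[0] == h[1]

    def test_empty_or_mismatched_splits_rejected(self, rng):
        X, y = self._toy_data(rng, n=8)
        model = build_model(TINY, n_outputs=1)
        with pytest.raises(ValueError):
            train(model, X[:0], y[:0], X, y)
        with pytest.raises(ValueError):
            train(model, X, y[:4], X, y)


class TestEvaluate:
    class _Oracle:
        """Stub model returning labels (optionally transformed)."""

        def __init__(self, y, f=lambda v: v):
            self.y, self.f = y, f

        def forward(self, X, training=False):
            n = len(X)
            out = self.f(self.y[self._i : self._i + n])
            self._i += n
            return out

        _i = 0

    def test_perfect_predictions(self, rng):
        y = rng.random((40, 1))
        rep = evaluate(self._Oracle(y), np.zeros((40, 8, 8, 1)), y)
        assert rep.mae == 0.0 and rep.spearman == 1.0
        assert rep.pearson == pytest.approx(1.0, abs=1e-12)

    def test_constant_bias_keeps_rank_correlation(self, rng):
        y = rng.random((40, 1))
        rep = evaluate(self._Oracle(y, lambda v: v + 0.25),
                       np.zeros((40, 8, 8, 1)), y)
        assert rep.mae == pytest.approx(0.25, abs=1e-7)
        assert rep.spearman == 1.0

    def test_sign_flip_gives_negative_rho(self, rng):
        y = rng.random((40, 1))
        rep = evaluate(self._Oracle(y, lambda v: -v), np.zeros((40, 8, 8, 1)), y)
        assert rep.spearman == -1.0

    def test_constant_predictions_warn(self, rng):
        y = rng.random((20, 1))
        with pytest.warns(UserWarning, match="constant"):
            rep = evaluate(self._Oracle(y, lambda v: np.zeros_like(v)),
                           np.zeros((20, 8, 8, 1)), y)
        assert rep.spearman == 0.0 and rep.pearson == 0.0


class TestLabelScaler:
    def test_roundtrip_and_gmsd_flip(self, rng):
        y = np.column_stack([rng.random(50), rng.random(50) * 0.3])
        scaler = LabelScaler.fit(y, ("SSIM", "GMSD"))
        scaled = scaler.transform(y)
        assert scaled.min() >= 0 and scaled.max() <= 1
        # lower-better GMSD is negated: its best (smallest) raw value maps to 1
        best_gmsd = np.argmin(y[:, 1])
        assert scaled[best_gmsd, 1] == pytest.approx(1.0)
        assert np.allclose(scaler.inverse(scaled), y, atol=1e-6)


class TestGradCAM:
    def test_map_shape_and_range(self, rng):
        model = build_model(TINY, n_outputs=2, seed=1)
        cam = gradcam(model, rng.random((32, 32)), output_index=1)
        assert cam.shape == (32, 32)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_mean_of_one_channel_head_recovers_that_channel(self, rng):
        conv = Conv2d(1, 3, 3, padding=1, rng=np.random.default_rng(0))
        net = _RegressorNet(
            [conv, ReLU(), GlobalAvgPool(), Linear(3, 1, rng=np.random.default_rng(1))],
            final_conv_index=1,
        )
        head = net.layers[-1]
        head.params["W"][...] = 0.0
        head.params["W"][0, 1] = 1.0  # output = mean of ReLU channel 1
        x = rng.random((16, 16))
        cam = gradcam(net, x)
        act = np.maximum(conv.forward(x[None, :, :, None].astype(np.float32)), 0)[0, :, :, 1]
        expected = (act - act.min()) / (act.max() - act.min())
        assert np.allclose(cam, expected, atol=1e-5)

    def test_out_of_range_output_index(self, rng):
        model = build_model(TINY, n_outputs=1)
        with pytest.raises(IndexError):
            gradcam(model, rng.random((32, 32)), output_index=3)
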