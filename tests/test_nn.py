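"""Network kernel: gradient correctness, forward contracts, determinism."""

import numpy as np
import pytest

from lvdlnet.models import ModelConfig, build_dl_libs, build_dl_vnir, build_lvdlnet
from lvdlnet.nn.layers import (
    BatchNorm1d,
    BiLSTM,
    Dense,
    LineConv,
    cross_entropy,
    softmax,
)

RNG = np.random.default_rng(123)
EPS = 1e-6


def numeric_grad(fn, arr):
    g = np.zeros_like(arr)
    for idx in np.ndindex(arr.shape):
        orig = arr[idx]
        arr[idx] = orig + EPS
        fp = fn()
        arr[idx] = orig - EPS
        fm = fn()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * EPS)
    return g


def check_layer(layer, x, train=True, tol=1e-7):
    """Backward pass vs central differences, on input and all parameters."""
    dout = RNG.normal(size=layer.forward(x, train).shape)

    def loss():
        return float((layer.forward(x, train) * dout).sum())

    dx = layer.backward(dout)
    np.testing.assert_allclose(numeric_grad(loss, x), dx, atol=tol)
    layer.forward(x, train)
    layer.backward(dout)
    for name, p in layer.params.items():
        np.testing.assert_allclose(
            numeric_grad(loss, p), layer.grads[name], atol=tol, err_msg=name
        )


def test_dense_gradients():
    check_layer(Dense(5, 3, RNG), RNG.normal(size=(7, 5)))


def test_batchnorm_gradients_train_mode():
    bn = BatchNorm1d(4)
    # running stats drift between finite-difference evaluations is harmless:
    # train-mode output depends only on batch stats
    check_layer(bn, RNG.normal(size=(9, 4)))


def test_lineconv_gradients():
    check_layer(LineConv(6, RNG), RNG.normal(size=(4, 5, 6)))


def test_bilstm_gradients():
    check_layer(BiLSTM(2, 4, RNG), RNG.normal(size=(3, 7, 2)), tol=1e-6)


def test_full_model_loss_gradient():
    """End-to-end gradient of the fused model's cross-entropy, spot-checked
    against finite differences on a few parameters of each component."""
    cfg = ModelConfig(
        n_lines=4, kernel_width=3, n_vnir_features=5, lstm_hidden=3,
        dense=4, fusion_dim=4, dropout=0.0, seed=5,
    )
    net = build_lvdlnet(cfg)
    rng = np.random.default_rng(0)
    xl = rng.normal(size=(6, 4, 3))
    xv = rng.normal(size=(6, 5))
    y = rng.integers(0, 6, size=6)

    def loss():
        return cross_entropy(net.forward((xl, xv), train=True), y)[0]

    base, dlogits = cross_entropy(net.forward((xl, xv), train=True), y)
    net.backward(dlogits)
    for layer in [net.libs.conv, net.libs.rnn, net.vnir.fc, net.proj_libs, net.out]:
        for name, p in layer.params.items():
            flat = p.reshape(-1)
            n_probe = min(3, flat.size)
            for j in np.random.default_rng(1).choice(flat.size, size=n_probe, replace=False):
                orig = flat[j]
                flat[j] = orig + EPS
                fp = loss()
                flat[j] = orig - EPS
                fm = loss()
                flat[j] = orig
                num = (fp - fm) / (2 * EPS)
                ana = layer.grads[name].reshape(-1)[j]
                assert num == pytest.approx(ana, abs=1e-6), (type(layer).__name__, name)


class TestForwardContracts:
    def test_libs_model_probability_contract(self):
        net = build_dl_libs(ModelConfig(seed=0))
        p = net.predict_proba(np.zeros((18, 14)))
        assert p.shape == (1, 6)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        batch = net.predict_proba(np.zeros((5, 18, 14)))
        np.testing.assert_allclose(batch.sum(axis=1), 1.0, atol=1e-6)

    def test_libs_model_rejects_wrong_line_count(self):
        net = build_dl_libs(ModelConfig(seed=0))
        with pytest.raises(ValueError, match="18"):
            net.predict_proba(np.zeros((17, 14)))

    def test_vnir_model_contract_and_shape_error(self):
        net = build_dl_vnir(ModelConfig(seed=0))
        p = net.predict_proba(np.zeros((32, 370)))
        assert p.shape == (32, 6)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        with pytest.raises(ValueError, match="370"):
            net.predict_proba(np.zeros((4, 369)))

    def test_fused_model_contract(self):
        net = build_lvdlnet(ModelConfig(seed=0))
        p = net.predict_proba((np.zeros((3, 18, 14)), np.zeros((3, 370))))
        assert p.shape == (3, 6)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        with pytest.raises(ValueError):
            net.predict_proba((np.zeros((3, 18, 13)), np.zeros((3, 370))))

    def test_argmax_invariant_under_logit_shift(self):
        z = RNG.normal(size=(10, 6))
        assert np.array_equal(
            np.argmax(softmax(z), axis=1), np.argmax(softmax(z + 100.0), axis=1)
        )


class TestDeterminism:
    def test_same_seed_same_initial_parameters(self):
        a = build_dl_libs(ModelConfig(seed=3))
        b = build_dl_libs(ModelConfig(seed=3))
        for la, lb in zip(a.param_layers(), b.param_layers()):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])
        c = build_dl_libs(ModelConfig(seed=4))
        assert not np.array_equal(
            a.head.fc1.params["W"], c.head.fc1.params["W"]
        )

    def test_inference_repeatable_with_dropout_disabled(self):
        net = build_dl_vnir(ModelConfig(seed=0, dropout=0.5))
        x = RNG.normal(size=(8, 370))
        np.testing.assert_array_equal(net.predict_proba(x), net.predict_proba(x))


def test_fusion_add_dimension_matches_config():
    cfg = ModelConfig(seed=0, fusion_dim=17)
    net = build_lvdlnet(cfg)
    assert net.proj_libs.params["W"].shape[1] == 17
    assert net.proj_vnir.params["W"].shape[1] == 17
    assert net.out.params["W"].shape == (17, 6)


def test_zeroed_vnir_projection_makes_output_libs_only():
    cfg = ModelConfig(seed=2, dropout=0.0)
    net = build_lvdlnet(cfg)
    net.proj_vnir.params["W"][...] = 0.0
    net.proj_vnir.params["b"][...] = 0.0
    rng = np.random.default_rng(0)
    xl = rng.normal(size=(4, 18, 14))
    p1 = net.predict_proba((xl, rng.normal(size=(4, 370))))
    p2 = net.predict_proba((xl, rng.normal(size=(4, 370)) * 50.0))
    np.testing.assert_allclose(p1, p2, atol=1e-12)
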