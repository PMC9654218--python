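"""Network primitives: analytic gradients vs central differences, layer
semantics and the optimiser."""

import numpy as np
import pytest

from multits.nn import (
    Activation, Adam, AvgPoolTime, BatchNorm, Dense, DepthwiseSpatialConv,
    Dropout, Flatten, MaxPoolTime, MultiBranch, Network, PointwiseConv,
    SEBlock, SpatialConv, TemporalConv, TemporalDepthwiseConv,
    binary_head_loss, softmax,
)

RNG = np.random.default_rng(12345)


def _num_grad(f, arr, idx, eps=1e-6):
    old = arr[idx]
    arr[idx] = old + eps
    up = f()
    arr[idx] = old - eps
    down = f()
    arr[idx] = old
    return (up - down) / (2 * eps)


def _check_layer_gradients(layer, x, n_checks=6):
    """Scalar loss = weighted sum of outputs; compare analytic grads of
    every parameter array and of the input against central differences."""
    w = RNG.standard_normal(layer.forward(x.copy(), train=True).shape)

    def loss():
        return float((layer.forward(x, train=True) * w).sum())

    base_out = layer.forward(x, train=True)
    dx = layer.backward(w.astype(x.dtype))
    assert base_out.dtype == x.dtype
    for name, arr in layer.params.items():
        g = layer.grads[name]
        for _ in range(n_checks):
            idx = tuple(RNG.integers(0, s) for s in arr.shape)
            num = _num_grad(loss, arr, idx)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-6), \
                f"{type(layer).__name__}.{name}{idx}"
    for _ in range(n_checks):
        idx = tuple(RNG.integers(0, s) for s in x.shape)
        num = _num_grad(loss, x, idx)
        assert dx[idx] == pytest.approx(num, rel=1e-4, abs=1e-6), \
            f"{type(layer).__name__} input{idx}"


def _rng_layer(seed=0):
    return np.random.default_rng(seed)


LAYER_CASES = [
    ("temporal_same", lambda: TemporalConv(2, 3, 5, "same", rng=_rng_layer(),
                                           dtype=np.float64), (2, 11, 2, 2)),
    ("temporal_valid", lambda: TemporalConv(2, 3, 4, "valid",
                                            rng=_rng_layer(),
                                            dtype=np.float64), (2, 11, 2, 2)),
    ("temporal_taploop", lambda: _taploop_conv(), (2, 11, 2, 2)),
    ("temporal_depthwise", lambda: TemporalDepthwiseConv(
        3, 4, "same", bias=True, rng=_rng_layer(), dtype=np.float64),
        (2, 9, 1, 3)),
    ("spatial", lambda: SpatialConv(4, 2, 3, rng=_rng_layer(),
                                    dtype=np.float64), (2, 7, 4, 2)),
    ("depthwise_spatial", lambda: DepthwiseSpatialConv(
        4, 3, 2, rng=_rng_layer(), dtype=np.float64), (2, 7, 4, 3)),
    ("pointwise", lambda: PointwiseConv(3, 2, rng=_rng_layer(),
                                        dtype=np.float64), (2, 7, 1, 3)),
    ("batchnorm", lambda: BatchNorm(3, dtype=np.float64), (3, 6, 2, 3)),
    ("avgpool", lambda: AvgPoolTime(3, 3), (2, 10, 2, 3)),
    ("avgpool_overlap", lambda: AvgPoolTime(4, 2), (2, 10, 2, 3)),
    ("maxpool", lambda: MaxPoolTime(3, 3), (2, 10, 2, 3)),
    ("relu", lambda: Activation("relu"), (2, 6, 2, 3)),
    ("elu", lambda: Activation("elu"), (2, 6, 2, 3)),
    ("square", lambda: Activation("square"), (2, 6, 2, 3)),
    ("log", lambda: Activation("log"), (2, 6, 2, 3)),
    ("se", lambda: SEBlock(6, r=3, rng=_rng_layer(), dtype=np.float64),
     (3, 5, 2, 6)),
    ("se_bias", lambda: SEBlock(6, r=3, bias=True, rng=_rng_layer(),
                                dtype=np.float64), (3, 5, 2, 6)),
    ("dense", lambda: Dense(8, 3, rng=_rng_layer(), dtype=np.float64),
     (4, 1, 1, 8)),
]


def _taploop_conv():
    conv = TemporalConv(2, 3, 5, "same", rng=_rng_layer(), dtype=np.float64)
    conv._COLS_LIMIT = 0  # force the memory-guarded fallback path
    return conv


@pytest.mark.parametrize("name,make,shape",
                         LAYER_CASES, ids=[c[0] for c in LAYER_CASES])
def test_layer_gradients_match_central_differences(name, make, shape):
    layer = make()
    x = RNG.standard_normal(shape)
    if name == "log":
        x = np.abs(x) + 0.5  # stay away from the clip point
    if name in ("maxpool", "relu"):
        x += 0.05 * np.sign(x)  # avoid kink/tie neighbourhoods
    _check_layer_gradients(layer, x)


def test_multibranch_gradients_and_concat_width():
    branches = [[TemporalConv(1, 2, k, "same", rng=_rng_layer(k),
                              dtype=np.float64)] for k in (1, 3, 5)]
    mb = MultiBranch(branches)
    x = RNG.standard_normal((2, 8, 2, 1))
    assert mb.forward(x).shape == (2, 8, 2, 6)
    assert mb.out_shape((8, 2, 1)) == (8, 2, 6)
    _check_layer_gradients(mb, x)


class TestLayerSemantics:
    def test_same_padding_preserves_time_length(self):
        for k in (1, 2, 5, 8):
            conv = TemporalConv(1, 2, k, "same", dtype=np.float64)
            assert conv.forward(np.zeros((1, 13, 2, 1))).shape[1] == 13

    def test_identity_construction_reproduces_relu_input(self):
        # one branch, one filter, kernel length 1, weight 1, bias 0
        conv = TemporalConv(1, 1, 1, "same", dtype=np.float64)
        conv.params["W"][:] = 1.0
        conv.params["b"][:] = 0.0
        x = RNG.standard_normal((2, 9, 3, 1))
        relu = Activation("relu")
        np.testing.assert_allclose(relu.forward(conv.forward(x)),
                                   np.maximum(x, 0))

    def test_depthwise_one_hot_selects_channel(self):
        # depthwise weights one-hot on channel 1 reproduce that channel's
        # temporal features (direct tensor-arithmetic oracle)
        dw = DepthwiseSpatialConv(3, 2, 1, bias=True, dtype=np.float64)
        dw.params["W"][:] = 0.0
        dw.params["W"][1, :, 0] = 1.0
        dw.params["b"][:] = 0.0
        x = RNG.standard_normal((2, 5, 3, 2))
        out = dw.forward(x)
        np.testing.assert_allclose(out[:, :, 0, :], x[:, :, 1, :])

    def test_se_gates_bounded_and_shrinking(self):
        se = SEBlock(8, r=4, rng=_rng_layer(1), dtype=np.float64)
        x = RNG.standard_normal((4, 6, 2, 8))
        y = se.forward(x)
        assert np.all(se.gates > 0) and np.all(se.gates < 1)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)

    def test_se_zero_final_weights_halve_input(self):
        se = SEBlock(8, r=4, rng=_rng_layer(2), dtype=np.float64)
        se.params["W2"][:] = 0.0  # sigmoid(0) = 0.5 for every gate
        x = RNG.standard_normal((3, 6, 2, 8))
        np.testing.assert_allclose(se.forward(x), x / 2)

    def test_se_bottleneck_width(self):
        assert SEBlock(96, r=16).bottleneck == 6
        assert SEBlock(8, r=16).bottleneck == 1

    def test_batchnorm_normalises_then_uses_running_stats(self):
        bn = BatchNorm(2, momentum=0.0, dtype=np.float64)
        x = RNG.standard_normal((50, 10, 1, 2)) * 3 + 1
        y = bn.forward(x, train=True)
        assert np.allclose(y.mean(axis=(0, 1, 2)), 0, atol=1e-7)
        assert np.allclose(y.std(axis=(0, 1, 2)), 1, atol=1e-2)
        y_eval = bn.forward(x, train=False)  # momentum 0: stats = last batch
        np.testing.assert_allclose(y_eval, y, atol=1e-6)

    def test_pool_values(self):
        x = np.arange(8, dtype=np.float64).reshape(1, 8, 1, 1)
        np.testing.assert_allclose(
            AvgPoolTime(4, 4).forward(x)[0, :, 0, 0], [1.5, 5.5])
        np.testing.assert_allclose(
            MaxPoolTime(4, 4).forward(x)[0, :, 0, 0], [3.0, 7.0])

    def test_dropout_identity_at_eval(self):
        drop = Dropout(0.5, seed=3)
        x = RNG.standard_normal((2, 5, 1, 3))
        np.testing.assert_array_equal(drop.forward(x, train=False), x)
        masked = drop.forward(x, train=True)
        assert np.any(masked == 0)

    def test_zero_weight_softmax_head_is_uniform(self):
        dense = Dense(6, 3, dtype=np.float64)
        dense.params["W"][:] = 0.0
        net = Network([Flatten(), dense], n_classes=3)
        p = net.predict_proba(RNG.standard_normal((4, 2, 3, 1)))
        np.testing.assert_allclose(p, 1 / 3, atol=1e-12)


def test_adam_fits_logistic_regression():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 1, 1, 2)).astype(np.float64)
    y = (X[:, 0, 0, 0] + X[:, 0, 0, 1] > 0).astype(float)
    net = Network([Flatten(), Dense(2, 1, rng=rng, dtype=np.float64)],
                  n_classes=2)
    opt = Adam(net, lr=0.05)
    first = net.loss_and_grad(X, y)
    for _ in range(200):
        net.loss_and_grad(X, y)
        opt.step()
    logits = net.forward(X, train=False)
    _, _ = binary_head_loss(logits, y)
    acc = np.mean((logits[:, 0] > 0) == y)
    assert acc > 0.95
    assert net.loss_and_grad(X, y) < first / 3


def test_softmax_rows_sum_to_one():
    z = RNG.standard_normal((5, 3)) * 10
    np.testing.assert_allclose(softmax(z).sum(axis=1), 1.0, rtol=1e-9)
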