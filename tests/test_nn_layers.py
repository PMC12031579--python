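"""Numerical checks of the layer primitives: forward passes against
independent references (scipy correlation) and backward passes against
central finite differences in float64."""

import numpy as np
import pytest
from scipy.signal import correlate

from cqtnet.nn.layers import (
    LSTM,
    Adam,
    Conv1d,
    Dense,
    Dropout,
    MaxPool2,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

RNG = np.random.default_rng(1234)


def numeric_grad(f, x, dy, eps=1e-6):
    """Central-difference gradient of sum(f(x) * dy) at a few coordinates."""
    coords = [tuple(RNG.integers(0, s) for s in x.shape) for _ in range(6)]
    grads = {}
    for c in coords:
        xp, xm = x.copy(), x.copy()
        xp[c] += eps
        xm[c] -= eps
        grads[c] = ((f(xp) * dy).sum() - (f(xm) * dy).sum()) / (2 * eps)
    return grads


@pytest.mark.parametrize(
    "cin,cout,k,length",
    [(1, 4, 7, 60), (3, 5, 9, 47), (6, 4, 90, 130)],  # direct and FFT paths
)
class TestConv1d:
    def test_forward_matches_scipy_correlate(self, cin, cout, k, length):
        conv = Conv1d(cin, cout, k, RNG, dtype=np.float64)
        x = RNG.normal(size=(2, cin, length))
        y = conv.forward(x)
        for b in range(2):
            for o in range(cout):
                ref = sum(
                    correlate(x[b, ci], conv.w[o, ci], mode="valid")
                    for ci in range(cin)
                ) + conv.b[o]
                np.testing.assert_allclose(y[b, o], ref, atol=1e-10)

    def test_gradients_match_finite_differences(self, cin, cout, k, length):
        conv = Conv1d(cin, cout, k, RNG, dtype=np.float64)
        x = RNG.normal(size=(2, cin, length))
        y = conv.forward(x)
        dy = RNG.normal(size=y.shape)
        dx = conv.backward(dy)
        for c, num in numeric_grad(lambda v: conv.forward(v), x, dy).items():
            assert dx[c] == pytest.approx(num, abs=1e-6)
        for c, num in numeric_grad(
            lambda w: _with_weights(conv, w, x), conv.w, dy
        ).items():
            assert conv.grads[0][c] == pytest.approx(num, abs=1e-6)


def _with_weights(conv, w, x):
    orig = conv.w.copy()
    conv.w[...] = w
    y = conv.forward(x)
    conv.w[...] = orig
    return y


class TestPoolAndActivations:
    def test_pool_halves_and_floors_odd_lengths(self):
        pool = MaxPool2()
        y = pool.forward(np.arange(14.0).reshape(1, 2, 7))
        assert y.shape == (1, 2, 3)  # trailing odd sample dropped
        np.testing.assert_array_equal(y[0, 0], [1, 3, 5])

    def test_pool_backward_routes_to_maxima(self):
        pool = MaxPool2()
        x = np.array([[[1.0, 4.0, 2.0, 2.0, 9.0, 0.0]]])
        y = pool.forward(x)
        dx = pool.backward(np.ones_like(y))
        np.testing.assert_array_equal(dx, [[[0, 1, 1, 0, 1, 0]]])

    def test_pool_tie_goes_left(self):
        pool = MaxPool2()
        pool.forward(np.array([[[5.0, 5.0]]]))
        dx = pool.backward(np.array([[[1.0]]]))
        np.testing.assert_array_equal(dx, [[[1.0, 0.0]]])

    def test_relu_gradient_mask(self):
        relu = ReLU()
        x = np.array([[-1.0, 0.0, 2.0]])
        y = relu.forward(x)
        np.testing.assert_array_equal(y, [[0, 0, 2]])
        np.testing.assert_array_equal(relu.backward(np.ones_like(x)), [[0, 0, 1]])

    def test_dropout_identity_at_inference_and_scaling_in_training(self):
        drop = Dropout(0.5)
        x = np.ones((4, 1000))
        np.testing.assert_array_equal(drop.forward(x, training=False), x)
        y = drop.forward(x, training=True, rng=np.random.default_rng(0))
        kept = y != 0
        assert np.all(y[kept] == 2.0)  # inverted scaling by 1/(1-rate)
        assert 0.4 < kept.mean() < 0.6


class TestLSTM:
    def test_shapes_and_tanh_range(self):
        lstm = LSTM(6, 5, RNG, dtype=np.float64)
        x = RNG.normal(size=(3, 11, 6))
        y = lstm.forward(x)
        assert y.shape == (3, 11, 5)  # all time steps returned
        assert np.all(np.abs(y) < 1.0)

    def test_gradients_match_finite_differences(self):
        lstm = LSTM(4, 3, RNG, dtype=np.float64)
        x = RNG.normal(size=(2, 7, 4))
        dy = RNG.normal(size=(2, 7, 3))
        dx = lstm.backward(dy) if lstm.forward(x) is not None else None
        for c, num in numeric_grad(lambda v: lstm.forward(v), x, dy).items():
            assert dx[c] == pytest.approx(num, abs=1e-6)
        # weight gradients
        lstm.zero_grad()
        lstm.forward(x)
        lstm.backward(dy)
        for p_idx, p in enumerate(lstm.params):
            c = tuple(RNG.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[c]
            p[c] = orig + eps
            up = (lstm.forward(x) * dy).sum()
            p[c] = orig - eps
            down = (lstm.forward(x) * dy).sum()
            p[c] = orig
            assert lstm.grads[p_idx][c] == pytest.approx(
                (up - down) / (2 * eps), abs=1e-5
            )


class TestHeadAndOptimizer:
    def test_dense_gradients(self):
        dense = Dense(5, 3, RNG, dtype=np.float64)
        x = RNG.normal(size=(4, 5))
        dy = RNG.normal(size=(4, 3))
        dense.forward(x)
        dx = dense.backward(dy)
        np.testing.assert_allclose(dx, dy @ dense.w.T)
        np.testing.assert_allclose(dense.grads[0], x.T @ dy)

    def test_softmax_cross_entropy_value_and_gradient(self):
        logits = np.array([[2.0, -1.0], [0.0, 0.0]])
        labels = np.array([0, 1])
        loss, dlogits = softmax_cross_entropy(logits, labels)
        p = softmax(logits)
        expected = -(np.log(p[0, 0]) + np.log(p[1, 1])) / 2
        assert loss == pytest.approx(expected)
        num = numeric_grad(
            lambda l: np.array(
                [softmax_cross_entropy(l, labels)[0]]
            ),
            logits,
            np.ones(1),
        )
        for c, g in num.items():
            assert dlogits[c] == pytest.approx(g, abs=1e-7)

    def test_adam_reduces_quadratic(self):
        w = np.array([5.0, -3.0])
        opt = Adam([w], lr=0.1)
        for _ in range(300):
            opt.step([2 * w])  # gradient of ||w||^2
        assert np.abs(w).max() < 1e-2
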