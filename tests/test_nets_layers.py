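import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cytocoral.errors import ContractError
from cytocoral.nets import (Conv2D, Dense, Dropout, Flatten, MaxPool2x2, ReLU,
                            Sequential, Upsample2x, conv_forward, maxpool2x2,
                            relu)


# ---------------------------------------------------------------------------
# independent oracles

def conv_oracle(inputs, kernels, biases, activation):
    """Naive quadruple-loop valid cross-correlation."""
    K = np.asarray(kernels, dtype=float)
    n_in, n_out, kh, kw = K.shape
    H, W = inputs[0].shape
    oh, ow = H - kh + 1, W - kw + 1
    outs = []
    for j in range(n_out):
        A = np.zeros((oh, ow))
        for a in range(oh):
            for b in range(ow):
                s = 0.0
                for i in range(n_in):
                    for p in range(kh):
                        for q in range(kw):
                            s += inputs[i][a + p, b + q] * K[i, j, p, q]
                A[a, b] = s + biases[j]
        outs.append(activation(A))
    return outs


def pool_oracle(m):
    h, w = m.shape[0] // 2, m.shape[1] // 2
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = m[2 * i:2 * i + 2, 2 * j:2 * j + 2].max()
    return out


# ---------------------------------------------------------------------------
# functional contracts

class TestRelu:
    def test_negative_maps_to_zero(self):
        assert relu(-1) == 0

    def test_positive_passes_through(self):
        assert relu(3) == 3

    def test_zero_boundary(self):
        assert relu(0) == 0

    @given(arrays(np.float64, (4, 4), elements=st.floats(-10, 10)))
    def test_elementwise_max(self, x):
        assert np.array_equal(relu(x), np.maximum(x, 0))


class TestMaxPool:
    def test_two_by_two(self):
        assert maxpool2x2(np.array([[1, 2], [3, 4]])) == np.array([[4]])

    def test_constant_matrix(self):
        assert np.array_equal(maxpool2x2(np.full((4, 4), 2.5)),
                              np.full((2, 2), 2.5))

    def test_four_by_four_distinct_vs_oracle(self):
        m = np.arange(16, dtype=float).reshape(4, 4)
        rng = np.random.default_rng(0)
        m = m[rng.permutation(4)][:, rng.permutation(4)]
        assert np.array_equal(maxpool2x2(m), pool_oracle(m))

    def test_odd_dims_floor(self):
        m = np.arange(25, dtype=float).reshape(5, 5)
        assert maxpool2x2(m).shape == (2, 2)
        assert np.array_equal(maxpool2x2(m), pool_oracle(m[:4, :4]))

    @given(arrays(np.float64, (6, 8), elements=st.floats(-5, 5)))
    @settings(max_examples=25)
    def test_matches_oracle(self, m):
        assert np.array_equal(maxpool2x2(m), pool_oracle(m))


class TestConvForward:
    def test_identity_1x1_kernel(self):
        x = np.arange(9, dtype=float).reshape(3, 3)
        out = conv_forward([x], np.ones((1, 1, 1, 1)), [0.0], "identity")
        assert np.array_equal(out[0], x)

    def test_hand_worked_2x2(self):
        # cross-correlation: 1*1 + 4*1 + bias 1 = 6, relu keeps it
        out = conv_forward([np.array([[1., 2.], [3., 4.]])],
                           np.array([[[[1., 0.], [0., 1.]]]]), [1.0], "relu")
        assert np.array_equal(out[0], np.array([[6.0]]))

    def test_large_negative_bias_saturates_relu(self):
        x = np.random.default_rng(0).random((5, 5))
        out = conv_forward([x], np.ones((1, 1, 3, 3)), [-100.0], "relu")
        assert np.array_equal(out[0], np.zeros((3, 3)))

    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(1)
        inputs = [rng.normal(size=(8, 8)) for _ in range(3)]
        K = rng.normal(size=(3, 2, 3, 3))
        b = rng.normal(size=2)
        got = conv_forward(inputs, K, b, "relu")
        exp = conv_oracle(inputs, K, b, lambda a: np.maximum(a, 0))
        for g, e in zip(got, exp):
            assert np.allclose(g, e, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            conv_forward([np.ones((4, 4))], np.ones((2, 1, 3, 3)), [0.0])


# ---------------------------------------------------------------------------
# batched layers against the same oracles

class TestConv2DLayer:
    def test_same_padding_matches_padded_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 6, 6, 2))
        layer = Conv2D(2, 3, 3, rng=rng)
        out = layer.forward(x)
        W, b = layer.params
        padded = [np.pad(x[0, :, :, c], 1) for c in range(2)]
        K = W.transpose(2, 3, 0, 1)  # (cin, cout, k, k)
        exp = conv_oracle(padded, K, b, lambda a: a)
        for j in range(3):
            assert np.allclose(out[0, :, :, j], exp[j], atol=1e-10)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 5, 5, 2))
        layer = Conv2D(2, 2, 3, rng=rng)

        def loss_of(xv):
            return float((layer.forward(xv) ** 2).sum())

        out = layer.forward(x)
        dx = layer.backward(2 * out)
        eps = 1e-6
        for idx in [(0, 2, 3, 1), (1, 0, 0, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (loss_of(xp) - loss_of(xm)) / (2 * eps)
            assert dx[idx] == pytest.approx(fd, abs=1e-4)

    def test_weight_gradient_finite_difference(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 4, 4, 1))
        layer = Conv2D(1, 1, 3, rng=rng)
        out = layer.forward(x)
        layer.backward(2 * out)
        W = layer.params[0]
        eps, idx = 1e-6, (1, 1, 0, 0)
        W[idx] += eps
        lp = float((layer.forward(x) ** 2).sum())
        W[idx] -= 2 * eps
        lm = float((layer.forward(x) ** 2).sum())
        W[idx] += eps
        assert layer.grads[0][idx] == pytest.approx((lp - lm) / (2 * eps),
                                                    abs=1e-4)


class TestPoolUpsampleLayers:
    def test_pool_matches_functional(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 6, 6, 3))
        out = MaxPool2x2().forward(x)
        for n in range(2):
            for c in range(3):
                assert np.array_equal(out[n, :, :, c],
                                      maxpool2x2(x[n, :, :, c]))

    def test_pool_backward_routes_to_argmax(self):
        x = np.array([[[[1.], [5.]], [[3.], [2.]]]])  # (1,2,2,1)
        layer = MaxPool2x2()
        layer.forward(x)
        dx = layer.backward(np.array([[[[7.]]]]))
        assert dx[0, 0, 1, 0] == 7.0 and dx.sum() == 7.0

    def test_upsample_inverts_spatial_reduction(self):
        x = np.random.default_rng(6).normal(size=(1, 3, 3, 2))
        up = Upsample2x().forward(x)
        assert up.shape == (1, 6, 6, 2)
        assert np.array_equal(up[0, ::2, ::2], x[0])
        # backward of upsample sums each 2x2 block
        dx = Upsample2x().backward(np.ones((1, 6, 6, 2)))
        assert np.array_equal(dx, np.full((1, 3, 3, 2), 4.0))


class TestDenseDropout:
    def test_dense_gradients(self):
        rng = np.random.default_rng(7)
        layer = Dense(4, 3, rng=rng)
        x = rng.normal(size=(5, 4))
        out = layer.forward(x)
        dx = layer.backward(np.ones_like(out))
        assert np.allclose(dx, np.ones((5, 3)) @ layer.params[0].T)
        assert np.allclose(layer.grads[0], x.T @ np.ones((5, 3)))

    def test_dropout_eval_is_identity(self):
        x = np.random.default_rng(8).normal(size=(3, 10))
        assert np.array_equal(Dropout(0.5).forward(x, train=False), x)

    def test_dropout_preserves_expectation(self):
        d = Dropout(0.2)
        d.rng = np.random.default_rng(9)
        x = np.ones((200, 200))
        out = d.forward(x, train=True)
        assert out.mean() == pytest.approx(1.0, abs=0.02)
        assert set(np.unique(out)) <= {0.0, 1.25}


def test_relu_network_outputs_finite_on_unit_inputs():
    rng = np.random.default_rng(10)
    model = Sequential([Conv2D(3, 4, 3, rng=rng), ReLU(), MaxPool2x2(),
                        Flatten(), Dense(4 * 8 * 8, 4, rng=rng)])
    x = rng.random((3, 16, 16, 3))
    assert np.isfinite(model.forward(x)).all()
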