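"""Oracle tests for the autodiff core and the model blocks."""

import numpy as np
import pytest

from microst.model import spatial_block_forward, temporal_block_forward
from microst.nn.autograd import Tensor, concat, einsum2
from microst.nn.layers import Linear, StackedLSTM, TemporalConvGLU


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestAutograd:
    @pytest.mark.parametrize(
        "op",
        [
            lambda a, b: a + b,
            lambda a, b: a * b,
            lambda a, b: a @ b,
            lambda a, b: (a @ b).tanh(),
            lambda a, b: (a @ b).sigmoid(),
            lambda a, b: (a @ b).relu(),
            lambda a, b: (a @ b).abs(),
        ],
    )
    def test_binary_op_gradients_match_numeric(self, op, rng):
        a = Tensor(rng.normal(size=(4, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(4, 4)) + 0.1, requires_grad=True)
        out = op(a, b)
        out.sum().backward()
        for t in (a, b):
            num = numeric_grad(lambda: float(op(a, b).sum().data), t.data)
            np.testing.assert_allclose(t.grad, num, atol=1e-5)

    def test_broadcast_add_gradient(self, rng):
        a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(4,)), requires_grad=True)
        (a + b).sum().backward()
        np.testing.assert_allclose(b.grad, np.full(4, 3.0))

    def test_getitem_scatter_gradient(self, rng):
        a = Tensor(rng.normal(size=(4, 6)), requires_grad=True)
        out = a[:, 1:4] * 2.0
        out.sum().backward()
        expected = np.zeros((4, 6))
        expected[:, 1:4] = 2.0
        np.testing.assert_allclose(a.grad, expected)

    def test_einsum2_contraction_gradient(self, rng):
        a = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        x = Tensor(rng.normal(size=(2, 3, 4, 2)), requires_grad=True)
        einsum2("ij,bjtc->bitc", a, x).sum().backward()
        num = numeric_grad(
            lambda: float(np.einsum("ij,bjtc->bitc", a.data, x.data).sum()),
            x.data,
        )
        np.testing.assert_allclose(x.grad, num, atol=1e-5)

    def test_concat_splits_gradient(self, rng):
        a = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=(2, 5)), requires_grad=True)
        out = concat([a, b], axis=1)
        (out * out).sum().backward()
        np.testing.assert_allclose(a.grad, 2 * a.data, atol=1e-12)
        np.testing.assert_allclose(b.grad, 2 * b.data, atol=1e-12)

    def test_pad_last_gradient(self, rng):
        a = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        a.pad_last(2).sum().backward()
        np.testing.assert_allclose(a.grad, np.ones((2, 3)))


def brute_force_causal_conv(x, weight, bias):
    """Sliding-window loop oracle for the causal temporal convolution."""
    b, c_in, n, t = x.shape
    c_out, _, k = weight.shape
    out = np.zeros((b, c_out, n, t))
    for bi in range(b):
        for co in range(c_out):
            for ni in range(n):
                for ti in range(t):
                    acc = bias[co]
                    for ci in range(c_in):
                        for j in range(k):  # tap j reads lag j
                            if ti - j >= 0:
                                acc += weight[co, ci, j] * x[bi, ci, ni, ti - j]
                    out[bi, co, ni, ti] = acc
    return out


class TestTemporalBlock:
    def test_identity_kernel_is_passthrough(self, rng):
        x = rng.normal(size=(2, 1, 3, 5))
        out = temporal_block_forward(
            x, np.ones((1, 1, 1)), np.zeros(1), activation="linear"
        )
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_zero_weights_bias_only(self, rng):
        x = rng.normal(size=(2, 1, 3, 5))
        out = temporal_block_forward(
            x, np.zeros((1, 1, 2)), np.array([3.5]), activation="linear"
        )
        np.testing.assert_allclose(out.data, 3.5)

    def test_hand_convolution_with_left_pad(self):
        x = np.array([1.0, 2.0, 3.0]).reshape(1, 1, 1, 3)
        out = temporal_block_forward(
            x, np.ones((1, 1, 2)), np.zeros(1), activation="linear"
        )
        np.testing.assert_allclose(out.data.ravel(), [1.0, 3.0, 5.0])

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=(2, 3, 4, 7))
        w = rng.normal(size=(5, 3, 3))
        b = rng.normal(size=5)
        out = temporal_block_forward(x, w, b, activation="linear")
        np.testing.assert_allclose(
            out.data, brute_force_causal_conv(x, w, b), atol=1e-10
        )

    def test_glu_is_linear_path_times_sigmoid_gate(self, rng):
        x = rng.normal(size=(1, 2, 3, 6))
        w = rng.normal(size=(4, 2, 2))  # 2 output channels under GLU
        b = rng.normal(size=4)
        pre = brute_force_causal_conv(x, w, b)
        expected = pre[:, :2] / (1 + np.exp(-pre[:, 2:]))
        out = temporal_block_forward(x, w, b, activation="glu")
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_causality(self, rng):
        # perturbing a future time step never changes earlier outputs
        x = rng.normal(size=(1, 1, 1, 8))
        w = rng.normal(size=(1, 1, 3))
        b = rng.normal(size=1)
        base = temporal_block_forward(x, w, b, activation="linear").data
        x2 = x.copy()
        x2[..., 5] += 10.0
        out2 = temporal_block_forward(x2, w, b, activation="linear").data
        np.testing.assert_allclose(out2[..., :5], base[..., :5], atol=1e-12)


class TestSpatialBlock:
    def test_identity_adjacency_passthrough(self, rng):
        x = rng.normal(size=(2, 4, 5, 3))
        out = spatial_block_forward(x, np.eye(4))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_hand_two_node_averaging(self):
        x = np.zeros((1, 2, 1, 1))
        x[0, 0, 0, 0] = 1.0
        x[0, 1, 0, 0] = 3.0
        out = spatial_block_forward(x, np.full((2, 2), 0.5))
        np.testing.assert_allclose(out.data.ravel(), [2.0, 2.0])

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=(2, 5, 3, 4))
        a = rng.normal(size=(5, 5))
        out = spatial_block_forward(x, a)
        expected = np.zeros_like(x)
        for i in range(5):
            for j in range(5):
                expected[:, i] += a[i, j] * x[:, j]
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_row_stochastic_preserves_node_constant_input(self, rng):
        a = rng.random((4, 4))
        a /= a.sum(axis=1, keepdims=True)
        x = np.broadcast_to(
            rng.normal(size=(2, 1, 3, 2)), (2, 4, 3, 2)
        ).copy()
        out = spatial_block_forward(x, a)
        np.testing.assert_allclose(out.data, x, atol=1e-10)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            spatial_block_forward(rng.normal(size=(1, 3, 2, 2)), np.eye(4))


class TestLSTM:
    def test_zero_input_zero_weights_fixed_point(self):
        lstm = StackedLSTM(1, 4, 3, np.random.default_rng(0))
        for _, p in lstm.named_parameters():
            p.data = np.zeros_like(p.data)
        out = lstm(Tensor(np.zeros((2, 6, 1))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(3, 5, 1))
        a = StackedLSTM(1, 4, 5, np.random.default_rng(9))(Tensor(x))
        b = StackedLSTM(1, 4, 5, np.random.default_rng(9))(Tensor(x))
        np.testing.assert_array_equal(a.data, b.data)

    def test_hidden_state_bounded(self, rng):
        lstm = StackedLSTM(1, 6, 5, np.random.default_rng(1))
        out = lstm(Tensor(rng.normal(scale=5.0, size=(4, 10, 1))))
        assert np.all(np.abs(out.data) < 1.0)

    def test_gradients_flow_to_all_layers(self, rng):
        lstm = StackedLSTM(1, 3, 4, np.random.default_rng(2))
        out = lstm(Tensor(rng.normal(size=(2, 6, 1))))
        out.sum().backward()
        for name, p in lstm.named_parameters():
            assert p.grad is not None and np.any(p.grad), name


class TestLinear:
    def test_affine_map(self, rng):
        lin = Linear(3, 2, np.random.default_rng(0))
        x = rng.normal(size=(4, 5, 3))
        out = lin(Tensor(x))
        np.testing.assert_allclose(
            out.data, x @ lin.weight.data + lin.bias.data, atol=1e-12
        )
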