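"""The autodiff substrate: op correctness against finite differences and
closed-form oracles, plus optimizer behaviour."""

import numpy as np
import pytest
from scipy.special import erf

from phosfx.nn import (
    Conv1d,
    GroupNorm,
    LayerNorm,
    Linear,
    Lookahead,
    MultiHeadAttention,
    RAdam,
    Tensor,
    attention,
    concat,
    gelu,
    glu,
    softmax,
)


def finite_difference(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = x[idx]
        x[idx] = old + eps
        fp = f()
        x[idx] = old - eps
        fm = f()
        x[idx] = old
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestGelu:
    def test_zero(self):
        assert gelu(np.array(0.0)).data == 0.0

    def test_limits(self):
        assert gelu(np.array(30.0)).data == pytest.approx(30.0, abs=1e-9)
        assert gelu(np.array(-10.0)).data == pytest.approx(0.0, abs=1e-9)

    def test_exact_erf_value(self):
        # x * Phi(x) at x=1 with Phi from the exact error function
        expected = 1.0 * 0.5 * (1 + erf(1 / np.sqrt(2)))
        assert gelu(np.array(1.0)).data == pytest.approx(expected, abs=1e-12)
        assert gelu(np.array(1.0)).data == pytest.approx(0.8413447, abs=1e-6)

    def test_gradient(self, rng):
        x = rng.standard_normal(7)
        t = Tensor(x, requires_grad=True)
        gelu(t).sum().backward()
        fd = finite_difference(lambda: float(gelu(Tensor(x)).sum().data), x)
        np.testing.assert_allclose(t.grad, fd, atol=1e-7)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            gelu(np.array([np.nan]))


class TestGlu:
    def test_identity_times_half(self, rng):
        X = rng.standard_normal((3, 4))
        out = glu(X, np.eye(4), np.zeros(4), np.zeros((4, 4)), np.zeros(4))
        np.testing.assert_allclose(out.data, 0.5 * X)

    def test_open_gate_limit(self, rng):
        X = rng.standard_normal((3, 4))
        W1 = rng.standard_normal((4, 4))
        b1 = rng.standard_normal(4)
        out = glu(X, W1, b1, np.zeros((4, 4)), np.full(4, 50.0))
        np.testing.assert_allclose(out.data, X @ W1 + b1, atol=1e-12)

    def test_integer_toy_hand_computation(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        W1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        W2 = np.array([[1.0, 1.0], [1.0, 1.0]])
        b1 = np.array([1.0, -1.0])
        b2 = np.array([0.0, 0.0])
        lin = X @ W1 + b1
        gate = 1 / (1 + np.exp(-(X @ W2 + b2)))
        np.testing.assert_allclose(glu(X, W1, b1, W2, b2).data, lin * gate, atol=1e-12)


class TestAttention:
    def test_saturated_softmax_selects_matching_key(self):
        k = np.eye(3) * 30.0
        v = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        q = np.array([[30.0, 0.0, 0.0]])
        out = attention(q, k, v).data
        np.testing.assert_allclose(out, v[:1], atol=1e-6)

    def test_uniform_scores_average_values(self, rng):
        q = np.zeros((2, 4))
        k = rng.standard_normal((5, 4))
        v = rng.standard_normal((5, 3))
        out = attention(q, k, v).data
        np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (2, 1)), atol=1e-12)

    def test_matches_brute_force_oracle(self):
        q = np.array([[1.0, 2.0], [0.0, 1.0]])
        k = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        v = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
        scores = q @ k.T / np.sqrt(2)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        w = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(attention(q, k, v).data, w @ v, atol=1e-12)

    def test_rows_sum_to_one_over_unmasked(self, rng):
        q = rng.standard_normal((3, 4))
        k = rng.standard_normal((6, 4))
        mask = np.array([1, 1, 0, 1, 0, 1], bool)
        w = softmax(Tensor(q @ k.T / 2.0), axis=-1, mask=mask).data
        np.testing.assert_allclose(w.sum(axis=1), 1.0)
        assert np.all(w[:, ~mask] < 1e-12)

    def test_all_masked_errors(self, rng):
        q = rng.standard_normal((1, 4))
        k = rng.standard_normal((3, 4))
        with pytest.raises(ValueError, match="mask"):
            attention(q, k, k, mask=np.zeros(3, bool))

    def test_gradients_flow(self, rng):
        q0 = rng.standard_normal((2, 4))
        k0 = rng.standard_normal((3, 4))
        v0 = rng.standard_normal((3, 4))
        q = Tensor(q0, requires_grad=True)
        attention(q, k0, v0).sum().backward()
        fd = finite_difference(
            lambda: float(attention(q0, k0, v0).sum().data), q0
        )
        np.testing.assert_allclose(q.grad, fd, atol=1e-6)


class TestLayerGradients:
    @pytest.mark.parametrize(
        "make",
        [
            lambda rng: (Linear(5, 3, rng), (4, 5)),
            lambda rng: (Conv1d(3, 4, 3, rng), (6, 3)),
            lambda rng: (LayerNorm(6), (4, 6)),
            lambda rng: (GroupNorm(2, 6), (1, 6)),
        ],
        ids=["linear", "conv1d", "layernorm", "groupnorm"],
    )
    def test_parameter_gradients_match_finite_differences(self, make, rng):
        layer, shape = make(np.random.default_rng(7))
        x = rng.standard_normal(shape)

        def run():
            return float((layer(Tensor(x)) * mult).sum().data)

        mult = rng.standard_normal(1)  # break symmetry in the scalarisation
        out = (layer(Tensor(x)) * mult).sum()
        layer.zero_grad()
        out.backward()
        for name, p in layer.parameters().items():
            fd = finite_difference(run, p.data)
            np.testing.assert_allclose(p.grad, fd, atol=1e-6, err_msg=name)

    def test_conv_same_length_and_hand_weights(self, rng):
        conv = Conv1d(2, 2, 7, rng)
        x = rng.standard_normal((9, 2))
        assert conv(Tensor(x)).shape == (9, 2)
        # one-hot kernel: output row j = input row j+offset (interior rows)
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0
        conv.weight.data[0, 0, 0] = 1.0  # leftmost tap (offset -3), channel 0->0
        out = conv(Tensor(x)).data
        np.testing.assert_allclose(out[3:, 0], x[:-3, 0], atol=1e-12)
        # hand-computed weighted 7-row sum in the middle of the sequence
        w = np.random.default_rng(0).standard_normal((7, 2, 2))
        conv.weight.data = w
        out = conv(Tensor(x)).data
        expected = sum(x[4 + o - 3] @ w[o] for o in range(7))
        np.testing.assert_allclose(out[4], expected, atol=1e-12)

    def test_multihead_attention_single_key(self, rng):
        mha = MultiHeadAttention(8, 2, rng)
        memory = rng.standard_normal((1, 8))
        q = rng.standard_normal((3, 8))
        out = mha(Tensor(q), Tensor(memory)).data
        # with one key, attention output is the value projection of that key
        v = memory @ mha.v_proj.weight.data + mha.v_proj.bias.data
        expected = np.tile(v @ mha.out_proj.weight.data + mha.out_proj.bias.data, (3, 1))
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestTensorOps:
    def test_concat_gradients(self, rng):
        a0 = rng.standard_normal((2, 3))
        b0 = rng.standard_normal((4, 3))
        a = Tensor(a0, requires_grad=True)
        b = Tensor(b0, requires_grad=True)
        (concat([a, b], axis=0) ** 2.0).sum().backward()
        np.testing.assert_allclose(a.grad, 2 * a0)
        np.testing.assert_allclose(b.grad, 2 * b0)

    def test_broadcast_gradients(self, rng):
        x0 = rng.standard_normal((3, 4))
        b0 = rng.standard_normal(4)
        b = Tensor(b0, requires_grad=True)
        ((Tensor(x0) + b) * (Tensor(x0) + b)).sum().backward()
        np.testing.assert_allclose(b.grad, (2 * (x0 + b0)).sum(axis=0))

    def test_softmax_rows_normalised(self, rng):
        x = rng.standard_normal((5, 7)) * 10
        s = softmax(Tensor(x), axis=-1).data
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-12)


class TestOptimizers:
    @staticmethod
    def _quadratic(params):
        # f(x) = 0.5 * ||x - target||^2 on a 2-parameter problem
        target = np.array([1.0, -2.0])
        x = params["x"]
        diff = x + Tensor(-target)
        return (diff * diff).sum() * 0.5

    def test_radam_descends_quadratic(self):
        x = Tensor(np.array([5.0, 5.0]), requires_grad=True)
        opt = RAdam({"x": x}, lr=0.1)
        first = float(self._quadratic({"x": x}).data)
        for _ in range(800):
            opt.zero_grad()
            loss = self._quadratic({"x": x})
            loss.backward()
            opt.step()
        assert float(loss.data) < 1e-3 < first

    def test_lookahead_k1_alpha1_matches_plain_radam(self):
        runs = {}
        for wrap in (False, True):
            x = Tensor(np.array([5.0, 5.0]), requires_grad=True)
            inner = RAdam({"x": x}, lr=0.1)
            opt = Lookahead(inner, k=1, alpha=1.0) if wrap else inner
            for _ in range(50):
                opt.zero_grad()
                self._quadratic({"x": x}).backward()
                opt.step()
            runs[wrap] = x.data.copy()
        np.testing.assert_allclose(runs[False], runs[True], atol=1e-12)

    def test_lookahead_interpolates_slow_weights(self):
        # plain inner trajectory for k steps
        y = Tensor(np.array([4.0, -3.0]), requires_grad=True)
        plain = RAdam({"x": y}, lr=0.2)
        for _ in range(2):
            plain.zero_grad()
            self._quadratic({"x": y}).backward()
            plain.step()
        fast_after_k = y.data.copy()
        # wrapped trajectory: after k=2 steps, weights = slow0 + 0.5*(fast - slow0)
        x = Tensor(np.array([4.0, -3.0]), requires_grad=True)
        start = x.data.copy()
        opt = Lookahead(RAdam({"x": x}, lr=0.2), k=2, alpha=0.5)
        for _ in range(2):
            opt.zero_grad()
            self._quadratic({"x": x}).backward()
            opt.step()
        np.testing.assert_allclose(x.data, start + 0.5 * (fast_after_k - start), atol=1e-12)
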