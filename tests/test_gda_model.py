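"""Dual-channel graph network: forwards, attention fusion, GRL, gradients."""

import numpy as np
import pytest

from atacgda.cell_graphs import build_knn_graph, normalized_adjacency, ppmi_operator
from atacgda.gda_model import (
    GradientReversal,
    agconv_forward,
    attention_fuse,
    classify,
    discriminate,
    gda_forward,
    init_gda_params,
    pgconv_forward,
)
from atacgda.training_inference import DomainDataset, _forward_losses_grads


# --- independent literal re-evaluations used as oracles -----------------------


def _gcn_oracle(S, H, W, b, relu=True):
    out = np.zeros((S.shape[0], W.shape[1]))
    prop = np.zeros((S.shape[0], H.shape[1]))
    for i in range(S.shape[0]):
        for j in range(S.shape[0]):
            prop[i] += S[i, j] * H[j]
    for i in range(S.shape[0]):
        out[i] = prop[i] @ W + b
        if relu:
            out[i] = np.where(out[i] > 0, out[i], 0.0)
    return out


def _fuse_oracle(Z_A, Z_P, W_Q, W_K, W_V):
    n, k = Z_A.shape
    out = np.zeros((n, k))
    for i in range(n):
        H = np.vstack([Z_A[i], Z_P[i]])  # 2 x k
        Q, K, V = H @ W_Q, H @ W_K, H @ W_V
        scores = Q @ K.T / np.sqrt(k)
        att = np.exp(scores - scores.max(axis=1, keepdims=True))
        att = att / att.sum(axis=1, keepdims=True)
        out[i] = (att @ V).mean(axis=0)
    return out


class TestAgConv:
    def test_identity_weights_average(self):
        S = np.full((2, 2), 0.5)
        out = agconv_forward(S, np.eye(2), np.eye(2), np.zeros(2))
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_relu_clamps_large_negative_bias(self):
        S = np.full((2, 2), 0.5)
        out = agconv_forward(S, np.eye(2), np.eye(2), np.full(2, -100.0))
        assert np.all(out == 0)

    def test_matches_literal_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = (rng.random((4, 4)) < 0.5).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            S = normalized_adjacency(A)
            H = rng.normal(size=(4, 3))
            W = rng.normal(size=(3, 2))
            b = rng.normal(size=2)
            np.testing.assert_allclose(
                agconv_forward(S, H, W, b), _gcn_oracle(S, H, W, b), atol=1e-10
            )


class TestPgConv:
    def test_same_operator_same_output(self):
        rng = np.random.default_rng(1)
        S = normalized_adjacency(np.array([[0, 1], [1, 0]]))
        H, W, b = rng.normal(size=(2, 3)), rng.normal(size=(3, 2)), rng.normal(size=2)
        np.testing.assert_array_equal(
            agconv_forward(S, H, W, b), pgconv_forward(S, H, W, b)
        )

    def test_identity_operator_reduces_to_dense_layer(self):
        rng = np.random.default_rng(2)
        H, W, b = rng.normal(size=(3, 4)), rng.normal(size=(4, 2)), rng.normal(size=2)
        np.testing.assert_allclose(
            pgconv_forward(np.eye(3), H, W, b), np.maximum(H @ W + b, 0)
        )

    def test_weight_sharing_is_aliasing(self):
        params = init_gda_params(4, 2, (3, 2), seed=0)
        # the two channels hold the same array object per layer: mutating the
        # shared weight changes both channel outputs
        S = np.eye(3)
        H = np.ones((3, 4))
        before_a = agconv_forward(S, H, params.gcn_weights[0], params.gcn_biases[0])
        before_p = pgconv_forward(S, H, params.gcn_weights[0], params.gcn_biases[0])
        params.gcn_weights[0] *= 2.0
        after_a = agconv_forward(S, H, params.gcn_weights[0], params.gcn_biases[0])
        after_p = pgconv_forward(S, H, params.gcn_weights[0], params.gcn_biases[0])
        np.testing.assert_array_equal(before_a, before_p)
        np.testing.assert_array_equal(after_a, after_p)
        assert not np.array_equal(before_a, after_a)


class TestAttentionFuse:
    def test_identical_channels_pass_through_value_projection(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(5, 4))
        W_Q, W_K, W_V = rng.normal(size=(3, 4, 4))
        np.testing.assert_allclose(attention_fuse(Z, Z, W_Q, W_K, W_V), Z @ W_V, atol=1e-12)

    def test_zero_logits_give_uniform_mixture(self):
        rng = np.random.default_rng(4)
        Z_A, Z_P = rng.normal(size=(2, 6, 4))
        out = attention_fuse(Z_A, Z_P, np.zeros((4, 4)), np.zeros((4, 4)), np.eye(4))
        np.testing.assert_allclose(out, (Z_A + Z_P) / 2, atol=1e-12)

    def test_matches_literal_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            Z_A, Z_P = rng.normal(size=(2, 5, 4))
            W_Q, W_K, W_V = rng.normal(size=(3, 4, 4))
            np.testing.assert_allclose(
                attention_fuse(Z_A, Z_P, W_Q, W_K, W_V),
                _fuse_oracle(Z_A, Z_P, W_Q, W_K, W_V),
                atol=1e-10,
            )


class TestGradientReversal:
    def test_forward_is_identity(self):
        x = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(GradientReversal(0.5).forward(x), x)

    def test_backward_scales_by_minus_lambda_exactly(self):
        # scalar toy model: loss(theta) = (grl(theta) - 1)^2
        theta = 0.3
        lam = 0.7
        grl = GradientReversal(lam)
        grad_no_grl = 2 * (theta - 1)
        assert grl.backward(np.array(grad_no_grl)) == -lam * grad_no_grl

    def test_lambda_zero_blocks_upstream_gradient(self):
        assert GradientReversal(0.0).backward(np.array(5.0)) == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            GradientReversal(-1.0)


class TestHeads:
    def test_classify_uniform_at_zero_weights(self):
        Z = np.random.default_rng(6).normal(size=(4, 3))
        post = classify(Z, np.zeros((3, 5)), np.zeros(5))
        np.testing.assert_allclose(post, 0.2)

    def test_classify_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        post = classify(rng.normal(size=(10, 3)), rng.normal(size=(3, 4)), rng.normal(size=4))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_classify_monotone_in_logit(self):
        Z = np.array([[1.0, 0.0]])
        W = np.eye(2)
        base = classify(Z, W, np.zeros(2))[0, 0]
        boosted = classify(Z * 2, W, np.zeros(2))[0, 0]
        assert boosted > base

    def test_discriminator_half_at_zero_weights(self):
        Z = np.random.default_rng(8).normal(size=(5, 4))
        p = discriminate(Z, np.zeros((4, 4)), np.zeros(4), np.zeros((4, 1)), np.zeros(1))
        np.testing.assert_allclose(p, 0.5)

    def test_discriminator_open_interval_and_complement(self):
        rng = np.random.default_rng(9)
        p = discriminate(
            rng.normal(size=(20, 4)) * 50,
            rng.normal(size=(4, 4)),
            rng.normal(size=4),
            rng.normal(size=(4, 1)),
            rng.normal(size=1),
        )
        assert np.all((p > 0) & (p < 1))
        np.testing.assert_allclose(p + (1 - p), 1.0)


def _toy_domains(seed=0):
    rng = np.random.default_rng(seed)

    def make(n, labels=None):
        X = rng.normal(size=(n, 5))
        g = build_knn_graph(X, k=2, metric="euclidean")
        return DomainDataset(g, normalized_adjacency(g.adjacency), ppmi_operator(g, 3, 10), labels=labels)

    return make(6, labels=np.array([0, 1, 0, 1, 1, 0])), make(5)


class TestFullNetworkGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of the composite objective agree with central FD.

        Head parameters descend L_cls + lam*L_grl; encoder parameters descend
        L_cls - lam*rate*L_grl because the reversal layer flips the
        adversarial gradient.
        """
        src, tgt = _toy_domains()
        params = init_gda_params(5, 2, (4, 3), seed=1)
        lam, rate = 0.7, 0.3
        _, _, grads = _forward_losses_grads(src, tgt, params, lam, rate)
        flat = params.flat()

        def objective(sign_for_encoder):
            lc, lg, _ = _forward_losses_grads(src, tgt, params, lam, rate)
            return lc + sign_for_encoder * lg

        eps = 1e-6
        for pi, (p, g) in enumerate(zip(flat, grads)):
            sign = -lam * rate if pi < 7 else lam  # encoder vs heads
            it = np.nditer(p, flags=["multi_index"])
            for _ in range(min(p.size, 10)):
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp = objective(sign)
                p[idx] = orig - eps
                lm = objective(sign)
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[idx]) <= 1e-4 * max(1.0, abs(fd))
                it.iternext()

    def test_forward_is_node_permutation_equivariant(self):
        src, _ = _toy_domains(seed=2)
        params = init_gda_params(5, 2, (4, 3), seed=3)
        Z, _ = gda_forward(src.S, src.S_P, src.X, params)
        perm = np.random.default_rng(4).permutation(src.n_nodes)
        P = np.eye(src.n_nodes)[perm]
        Zp, _ = gda_forward(P @ src.S @ P.T, P @ src.S_P @ P.T, P @ src.X, params)
        np.testing.assert_allclose(Zp, P @ Z, atol=1e-10)

    def test_forward_reproducible_bit_for_bit(self):
        src, tgt = _toy_domains(seed=5)
        p1 = init_gda_params(5, 2, (4, 3), seed=6)
        p2 = init_gda_params(5, 2, (4, 3), seed=6)
        Z1, _ = gda_forward(src.S, src.S_P, src.X, p1)
        Z2, _ = gda_forward(src.S, src.S_P, src.X, p2)
        np.testing.assert_array_equal(Z1, Z2)
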