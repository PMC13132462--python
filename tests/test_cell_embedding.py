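"""Stage-1 reconstruction network and cell-embedding extraction."""

import numpy as np
import pytest
import scipy.sparse as sp

from atacgda.cell_embedding import (
    EmbedderParams,
    bce_loss,
    extract_cell_embeddings,
    forward_accessibility,
    init_embedder,
    mlp_forward,
    train_cell_embedder,
)
from atacgda.io_formats import AccessibilityMatrix
from atacgda.sequence_encoding import PeakEmbeddingMatrix


def _am(dense):
    dense = np.asarray(dense, dtype=np.uint8)
    return AccessibilityMatrix(
        sp.csr_matrix(dense),
        [f"p{i}" for i in range(dense.shape[0])],
        [f"c{j}" for j in range(dense.shape[1])],
    )


class TestForwardAccessibility:
    def test_zero_logits_give_half(self):
        out = forward_accessibility(np.zeros((3, 2)), np.zeros((2, 4)), np.zeros(4))
        np.testing.assert_allclose(out, 0.5)

    def test_monotone_saturation(self):
        W = np.ones((1, 1))
        vals = [forward_accessibility(np.array([[x]]), W, np.zeros(1))[0, 0] for x in (2, 4, 8)]
        assert vals[0] < vals[1] < vals[2] < 1.0

    def test_closed_form_sigmoid(self):
        z = np.array([[1.0, 0.0]])
        W = np.array([[1.0, -1.0], [0.0, 0.0]])
        out = forward_accessibility(z, W, np.zeros(2))
        np.testing.assert_allclose(out, [[0.7310585786, 0.2689414214]], atol=1e-9)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            forward_accessibility(np.array([[np.nan]]), np.ones((1, 1)), np.zeros(1))


class TestBceLoss:
    def test_half_predictions_give_ln2(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert abs(bce_loss(np.full((2, 2), 0.5), y) - np.log(2)) < 1e-12

    def test_perfect_prediction_near_zero(self):
        y = np.array([[1.0, 0.0]])
        assert bce_loss(y, y) <= 1.1e-7

    def test_hand_computed_value(self):
        y = np.array([[1.0, 0.0]])
        yhat = np.array([[0.9, 0.2]])
        expected = (-np.log(0.9) - np.log(0.8)) / 2
        assert abs(bce_loss(yhat, y) - expected) < 1e-12

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        yhat = rng.random((4, 5))
        y = (rng.random((4, 5)) < 0.5).astype(float)
        assert bce_loss(yhat, y) >= 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestGradientCorrectness:
    def test_analytic_gradient_of_bce_wrt_output_weights(self):
        """Central finite differences on a 3-peak x 2-cell instance, rel err <= 1e-4."""
        rng = np.random.default_rng(1)
        z = rng.normal(size=(3, 4))
        W_o = rng.normal(size=(4, 2))
        b_o = rng.normal(size=2)
        y = (rng.random((3, 2)) < 0.5).astype(float)

        yhat = forward_accessibility(z, W_o, b_o)
        analytic = z.T @ ((yhat - y) / y.size)  # d BCE / d W_o

        eps = 1e-6
        for i in range(W_o.shape[0]):
            for j in range(W_o.shape[1]):
                orig = W_o[i, j]
                W_o[i, j] = orig + eps
                lp = bce_loss(forward_accessibility(z, W_o, b_o), y)
                W_o[i, j] = orig - eps
                lm = bce_loss(forward_accessibility(z, W_o, b_o), y)
                W_o[i, j] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - analytic[i, j]) <= 1e-4 * max(abs(fd), abs(analytic[i, j]), 1e-8)


@pytest.fixture(scope="module")
def small_training_problem():
    rng = np.random.default_rng(2)
    n_peaks, d_in, n_cells = 40, 16, 12
    X = rng.random((n_peaks, d_in))
    emb = PeakEmbeddingMatrix(X, [f"p{i}" for i in range(n_peaks)], "test")
    y = (rng.random((n_peaks, n_cells)) < 0.3).astype(np.uint8)
    return emb, _am(y)


class TestTrainCellEmbedder:
    def test_loss_history_finite_and_decreasing(self, small_training_problem):
        emb, am = small_training_problem
        _, hist = train_cell_embedder(emb, am, hidden_dims=(8, 4), epochs=30, seed=0)
        assert len(hist) == 30
        assert all(np.isfinite(hist))
        assert hist[-1] <= hist[0]

    def test_seeded_determinism(self, small_training_problem):
        emb, am = small_training_problem
        p1, h1 = train_cell_embedder(emb, am, hidden_dims=(8, 4), epochs=5, seed=7)
        p2, h2 = train_cell_embedder(emb, am, hidden_dims=(8, 4), epochs=5, seed=7)
        assert h1 == h2
        np.testing.assert_array_equal(p1.W_o, p2.W_o)
        for w1, w2 in zip(p1.hidden_weights, p2.hidden_weights):
            np.testing.assert_array_equal(w1, w2)

    def test_zero_epochs_returns_initial_params(self, small_training_problem):
        emb, am = small_training_problem
        params, hist = train_cell_embedder(emb, am, hidden_dims=(8, 4), epochs=0, seed=3)
        ref = init_embedder(emb.dim, am.n_cells, (8, 4), seed=3)
        assert hist == []
        np.testing.assert_array_equal(params.W_o, ref.W_o)

    def test_misaligned_peak_order_rejected(self, small_training_problem):
        emb, am = small_training_problem
        bad = PeakEmbeddingMatrix(emb.values, list(reversed(emb.peak_ids)), "test")
        with pytest.raises(ValueError, match="peak order"):
            train_cell_embedder(bad, am, epochs=1)


class TestExtractCellEmbeddings:
    def test_identity_output_weights_give_basis_vectors(self):
        d = 4
        params = EmbedderParams([], [], np.eye(d), np.zeros(d))
        emb = extract_cell_embeddings(params, [f"c{i}" for i in range(d)])
        np.testing.assert_array_equal(emb.values, np.eye(d))

    def test_row_j_is_column_j_and_round_trip(self):
        rng = np.random.default_rng(4)
        W_o = rng.normal(size=(5, 3))
        params = EmbedderParams([], [], W_o, np.zeros(3))
        emb = extract_cell_embeddings(params, ["a", "b", "c"])
        np.testing.assert_array_equal(emb.values, W_o.T)
        np.testing.assert_array_equal(emb.values.T, W_o)  # reassembly round trip

    def test_default_width_128(self, small_training_problem):
        emb, am = small_training_problem
        params, _ = train_cell_embedder(emb, am, epochs=0, seed=0)
        cells = extract_cell_embeddings(params, am.cell_barcodes)
        assert cells.dim == 128

    def test_barcode_count_mismatch(self):
        params = EmbedderParams([], [], np.eye(3), np.zeros(3))
        with pytest.raises(ValueError):
            extract_cell_embeddings(params, ["a", "b"])


class TestMlpForward:
    def test_relu_between_layers(self):
        params = EmbedderParams(
            [np.array([[1.0, -1.0]]), np.array([[1.0], [1.0]])],
            [np.zeros(2), np.zeros(1)],
            np.eye(1),
            np.zeros(1),
        )
        acts = mlp_forward(np.array([[2.0]]), params)
        np.testing.assert_allclose(acts[0], [[2.0, 0.0]])  # negative path clamped
        np.testing.assert_allclose(acts[1], [[2.0]])
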