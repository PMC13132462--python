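"""Stage 1: accessibility reconstruction and cell-embedding extraction.

A small MLP maps each peak's sequence embedding (width d') through hidden
layers 512-256-128 (ReLU) to a d=128 representation; a fully connected
sigmoid output head then predicts that peak's binary accessibility across all
N_cell cells of one domain:

    Yhat = sigmoid(Z_hidden @ W_o + b_o),   W_o in R^{d x N_cell}

trained with mean binary cross-entropy against the observed matrix. After
training, column j of W_o is taken as the d-dimensional embedding of cell j:
cells with similar accessibility profiles acquire similar readout columns
against the shared peak-representation basis. The training operation itself
is agnostic to domains; the pipeline trains one model whose output columns
span the reference and query cells together (see
``pipeline.embed_domains_joint``), so the extracted per-domain embeddings
share a comparable basis, and residual batch effects are handled by the graph
domain adaptation stage.

The forward/backward passes are written directly in numpy; gradients are
covered by finite-difference checks in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._optim import Adam, glorot
from .io_formats import AccessibilityMatrix
from .sequence_encoding import PeakEmbeddingMatrix

logger = logging.getLogger(__name__)

EPS = 1e-7  # probability clamp: the BCE is undefined at exactly 0/1


@dataclass
class EmbedderParams:
    """MLP weights plus the cell-readout head of one domain's embedder."""

    hidden_weights: list[np.ndarray]
    hidden_biases: list[np.ndarray]
    W_o: np.ndarray  # d x N_cell
    b_o: np.ndarray  # N_cell

    @property
    def d(self) -> int:
        return self.W_o.shape[0]

    @property
    def n_cells(self) -> int:
        return self.W_o.shape[1]

    def flat(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in zip(self.hidden_weights, self.hidden_biases):
            out += [w, b]
        return out + [self.W_o, self.b_o]


@dataclass
class CellEmbeddingMatrix:
    """Per-cell d-dimensional features extracted from the output-layer weights."""

    values: np.ndarray  # N_cell x d
    cell_barcodes: list[str]
    domain: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.cell_barcodes):
            raise ValueError("embedding rows must align with barcodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite cell embeddings")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def forward_accessibility(z_hidden: np.ndarray, W_o: np.ndarray, b_o: np.ndarray) -> np.ndarray:
    """Predicted accessibility: elementwise sigmoid of the linear readout."""
    z_hidden = np.asarray(z_hidden, dtype=np.float64)
    if not np.all(np.isfinite(z_hidden)):
        raise ValueError("non-finite hidden features")
    return _sigmoid(z_hidden @ W_o + b_o)


def bce_loss(yhat: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy over all peak-cell entries (clamped at 1e-7)."""
    yhat = np.asarray(yhat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if yhat.shape != y.shape:
        raise ValueError(f"shape mismatch: {yhat.shape} vs {y.shape}")
    p = np.clip(yhat, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def mlp_forward(X: np.ndarray, params: EmbedderParams) -> list[np.ndarray]:
    """Hidden activations [h_1, ..., h_L]; ReLU between layers, final layer included."""
    acts = []
    h = X
    for W, b in zip(params.hidden_weights, params.hidden_biases):
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    return acts


def init_embedder(
    d_in: int, n_cells: int, hidden_dims: tuple[int, ...], seed: int
) -> EmbedderParams:
    rng = np.random.default_rng(seed)
    dims = [d_in, *hidden_dims]
    Ws = [glorot(rng, dims[i], dims[i + 1]) for i in range(len(hidden_dims))]
    bs = [np.zeros(d) for d in hidden_dims]
    W_o = glorot(rng, hidden_dims[-1], n_cells)
    b_o = np.zeros(n_cells)
    return EmbedderParams(Ws, bs, W_o, b_o)


def train_cell_embedder(
    peak_embeddings: PeakEmbeddingMatrix,
    Y: AccessibilityMatrix,
    hidden_dims: tuple[int, ...] = (512, 256, 128),
    lr: float = 1e-3,
    epochs: int = 400,
    batch_size: int = 256,
    seed: int = 0,
) -> tuple[EmbedderParams, list[float]]:
    """Fit the reconstruction network by Adam on minibatches of peaks.

    Every minibatch carries all cells (the readout head is per-cell); the loss
    history holds one mean-BCE value per epoch. Fully deterministic given the
    seed. ``epochs=0`` returns the freshly initialized parameters.
    """
    if peak_embeddings.peak_ids != list(Y.peak_ids):
        raise ValueError("peak order of embeddings and accessibility matrix differ")
    X = peak_embeddings.values
    n_peaks = X.shape[0]
    params = init_embedder(X.shape[1], Y.n_cells, tuple(hidden_dims), seed)
    opt = Adam(params.flat(), lr=lr)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    history: list[float] = []
    Ycsr = Y.values.tocsr()

    for epoch in range(epochs):
        order = rng.permutation(n_peaks)
        total = 0.0
        for lo in range(0, n_peaks, batch_size):
            batch = order[lo : lo + batch_size]
            xb = X[batch]
            yb = np.asarray(Ycsr[batch].todense(), dtype=np.float64)

            # forward
            acts = mlp_forward(xb, params)
            h = acts[-1]
            yhat = forward_accessibility(h, params.W_o, params.b_o)
            loss = bce_loss(yhat, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf reconstruction loss at epoch {epoch}, batch offset {lo}"
                )
            total += loss * len(batch)

            # backward (sigmoid + BCE head, then ReLU MLP)
            scale = 1.0 / (len(batch) * Y.n_cells)
            dlogits = (yhat - yb) * scale
            gW_o = h.T @ dlogits
            gb_o = dlogits.sum(axis=0)
            dh = dlogits @ params.W_o.T
            gWs: list[np.ndarray] = []
            gbs: list[np.ndarray] = []
            for li in range(len(params.hidden_weights) - 1, -1, -1):
                inp = acts[li - 1] if li > 0 else xb
                da = dh * (acts[li] > 0)
                gWs.append(inp.T @ da)
                gbs.append(da.sum(axis=0))
                if li > 0:
                    dh = da @ params.hidden_weights[li].T
            gWs.reverse()
            gbs.reverse()
            grads: list[np.ndarray] = []
            for gw, gb in zip(gWs, gbs):
                grads += [gw, gb]
            grads += [gW_o, gb_o]
            opt.step(grads)
        history.append(total / n_peaks)
        if (epoch + 1) % 50 == 0:
            logger.info("embedder epoch %d/%d: bce=%.5f", epoch + 1, epochs, history[-1])
    return params, history


def extract_cell_embeddings(
    params: EmbedderParams, barcodes: list[str], domain: str = ""
) -> CellEmbeddingMatrix:
    """Cell j's embedding is column j of the trained output-weight matrix."""
    if len(barcodes) != params.n_cells:
        raise ValueError(
            f"{len(barcodes)} barcodes but the output layer has {params.n_cells} columns"
        )
    return CellEmbeddingMatrix(params.W_o.T.copy(), list(barcodes), domain)
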