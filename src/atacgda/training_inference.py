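"""Stage 2: joint adversarial training over both cell graphs and prediction.

Each epoch feeds ALL nodes of the source and target graphs through the shared
dual-channel network (full batch), evaluates the composite objective

    L = L_cls + lambda * L_grl

(source-node cross-entropy plus the domain-discriminator binary
cross-entropy over both domains, adversarial through gradient reversal), and
takes one Adam step. Target labels are never consumed here; evaluation takes
a separate held-out truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_recall_fscore_support,
)

from ._optim import Adam, SGDMomentum
from .cell_graphs import CellGraph
from .gda_model import EPS, GDAParams, classify, discriminate, gda_backward, gda_forward, init_gda_params


@dataclass
class DomainDataset:
    """Everything stage 2 needs about one domain: graph, operators, labels."""

    graph: CellGraph
    S: np.ndarray  # normalized adjacency operator
    S_P: np.ndarray  # normalized PPMI operator
    labels: np.ndarray | None = None  # int class indices (source only)
    domain: str = ""

    @property
    def X(self) -> np.ndarray:
        return self.graph.features

    @property
    def n_nodes(self) -> int:
        return self.graph.n_nodes


@dataclass
class TrainConfig:
    """Stage-2 hyperparameters (learning rate 3e-3, two GCN layers 100-16).

    ``grl_max_rate`` caps the gradient-reversal rate into the feature
    encoder: the rate warms up linearly as (epoch+1)/epochs and saturates at
    this cap, while the discriminator always trains at full strength. Without
    the cap the encoder wins the minimax game by anti-aligning the domains
    once the source classification loss is exhausted.
    """

    lr: float = 3e-3
    epochs: int = 100
    lam: float = 1.0
    hidden_dims: tuple[int, ...] = (100, 16)
    grl_max_rate: float = 0.05
    disc_steps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs < 0 or self.lam < 0:
            raise ValueError("need lr > 0, epochs >= 0, lambda >= 0")
        if self.grl_max_rate < 0:
            raise ValueError("grl_max_rate must be nonnegative")
        if self.disc_steps < 0:
            raise ValueError("disc_steps must be nonnegative")


class TrainingDiverged(RuntimeError):
    """Raised on a non-finite loss; carries the last finite parameter set."""

    def __init__(self, message: str, params: GDAParams, history: list[dict]):
        super().__init__(message)
        self.params = params
        self.history = history


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def cls_loss(posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class over source nodes."""
    posteriors = np.asarray(posteriors, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= posteriors.shape[1]:
        raise ValueError("label outside 0..C-1")
    p = np.clip(posteriors[np.arange(len(labels)), labels], EPS, 1.0)
    return float(-np.mean(np.log(p)))


def domain_loss(p_source_on_source: np.ndarray, p_source_on_target: np.ndarray) -> float:
    """Discriminator BCE: source nodes scored as source, target as target."""
    ps = np.clip(np.asarray(p_source_on_source, dtype=np.float64), EPS, 1.0 - EPS)
    pt = np.clip(np.asarray(p_source_on_target, dtype=np.float64), EPS, 1.0 - EPS)
    return float(-np.mean(np.log(ps)) - np.mean(np.log(1.0 - pt)))


def total_loss(cls: float, grl: float, lam: float) -> float:
    """Composite objective L = L_cls + lambda * L_grl."""
    return float(cls + lam * grl)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _forward_losses_grads(
    source: DomainDataset,
    target: DomainDataset,
    params: GDAParams,
    lam: float,
    grl_rate: float = 1.0,
):
    Z_s, cache_s = gda_forward(source.S, source.S_P, source.X, params)
    Z_t, cache_t = gda_forward(target.S, target.S_P, target.X, params)
    n_s, n_t = source.n_nodes, target.n_nodes
    labels = source.labels

    post_s = classify(Z_s, params.W_cls, params.b_cls)
    l_cls = cls_loss(post_s, labels)

    h_s = np.maximum(Z_s @ params.W_dom1 + params.b_dom1, 0.0)
    h_t = np.maximum(Z_t @ params.W_dom1 + params.b_dom1, 0.0)
    q_s = discriminate(Z_s, params.W_dom1, params.b_dom1, params.w_dom, params.b_dom)
    q_t = discriminate(Z_t, params.W_dom1, params.b_dom1, params.w_dom, params.b_dom)
    l_grl = domain_loss(q_s, q_t)

    # classifier head gradient (source only)
    one_hot = np.zeros_like(post_s)
    one_hot[np.arange(n_s), labels] = 1.0
    dlogits = (post_s - one_hot) / n_s
    gW_cls = Z_s.T @ dlogits
    gb_cls = dlogits.sum(axis=0)
    dZ_s = dlogits @ params.W_cls.T

    # discriminator parameters descend lambda * L_grl at full strength; the
    # gradient reversal layer flips and rate-scales what reaches the features
    ds_s = lam * (q_s - 1.0)[:, None] / n_s
    ds_t = lam * q_t[:, None] / n_t
    gw_dom = h_s.T @ ds_s + h_t.T @ ds_t
    gb_dom = np.array([ds_s.sum() + ds_t.sum()])
    dh_s = (ds_s @ params.w_dom.T) * (h_s > 0)
    dh_t = (ds_t @ params.w_dom.T) * (h_t > 0)
    gW_dom1 = Z_s.T @ dh_s + Z_t.T @ dh_t
    gb_dom1 = dh_s.sum(axis=0) + dh_t.sum(axis=0)
    dZ_s = dZ_s - grl_rate * (dh_s @ params.W_dom1.T)  # reversed sign
    dZ_t = -grl_rate * (dh_t @ params.W_dom1.T)

    g_s = gda_backward(dZ_s, cache_s, params)
    g_t = gda_backward(dZ_t, cache_t, params)
    shared = {k: g_s[k] + g_t[k] for k in g_s}
    grads = [
        shared["W1"], shared["b1"], shared["W2"], shared["b2"],
        shared["W_Q"], shared["W_K"], shared["W_V"],
        gW_cls, gb_cls, gW_dom1, gb_dom1, gw_dom, gb_dom,
    ]
    return l_cls, l_grl, grads


def _disc_grads(Z_s, Z_t, params: GDAParams, lam: float):
    """Discriminator-parameter gradients of lam * L_grl on fixed features."""
    n_s, n_t = Z_s.shape[0], Z_t.shape[0]
    h_s = np.maximum(Z_s @ params.W_dom1 + params.b_dom1, 0.0)
    h_t = np.maximum(Z_t @ params.W_dom1 + params.b_dom1, 0.0)
    q_s = discriminate(Z_s, params.W_dom1, params.b_dom1, params.w_dom, params.b_dom)
    q_t = discriminate(Z_t, params.W_dom1, params.b_dom1, params.w_dom, params.b_dom)
    ds_s = lam * (q_s - 1.0)[:, None] / n_s
    ds_t = lam * q_t[:, None] / n_t
    gw_dom = h_s.T @ ds_s + h_t.T @ ds_t
    gb_dom = np.array([ds_s.sum() + ds_t.sum()])
    dh_s = (ds_s @ params.w_dom.T) * (h_s > 0)
    dh_t = (ds_t @ params.w_dom.T) * (h_t > 0)
    gW_dom1 = Z_s.T @ dh_s + Z_t.T @ dh_t
    gb_dom1 = dh_s.sum(axis=0) + dh_t.sum(axis=0)
    return [gW_dom1, gb_dom1, gw_dom, gb_dom]


def train_gda(
    source: DomainDataset, target: DomainDataset, cfg: TrainConfig
) -> tuple[GDAParams, list[dict]]:
    """Joint full-batch adversarial training; returns parameters and loss history.

    Each epoch first refines the domain discriminator for ``cfg.disc_steps``
    extra steps on the current (fixed) fused features, keeping the critic
    near-optimal so that the reversed gradient points toward genuine domain
    confusion, then takes one joint step: classifier + discriminator heads
    descend Eq-style L_cls + lam * L_grl while the shared feature encoder
    receives the gradient-reversed adversarial signal scaled by the warm-up
    rate (capped at ``cfg.grl_max_rate``).
    """
    if source.labels is None:
        raise ValueError("source dataset carries no labels")
    if source.X.shape[1] != target.X.shape[1]:
        raise ValueError("source and target feature widths differ")
    n_classes = int(source.labels.max()) + 1
    params = init_gda_params(source.X.shape[1], n_classes, cfg.hidden_dims, cfg.seed)
    flat = params.flat()
    # encoder + classifier use momentum SGD so the capped adversarial gradient
    # keeps its small relative scale; the discriminator uses Adam to track the
    # moving feature distribution quickly
    opt_main = SGDMomentum(flat[:9], lr=cfg.lr)
    opt_disc = Adam(flat[9:], lr=cfg.lr)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        rate = min((epoch + 1) / max(cfg.epochs, 1), cfg.grl_max_rate)
        if cfg.lam > 0 and cfg.disc_steps > 0:
            Z_s, _ = gda_forward(source.S, source.S_P, source.X, params)
            Z_t, _ = gda_forward(target.S, target.S_P, target.X, params)
            for _ in range(cfg.disc_steps):
                opt_disc.step(_disc_grads(Z_s, Z_t, params, cfg.lam))
        l_cls, l_grl, grads = _forward_losses_grads(source, target, params, cfg.lam, rate)
        loss = total_loss(l_cls, l_grl, cfg.lam)
        if not np.isfinite(loss):
            raise TrainingDiverged(f"non-finite loss at epoch {epoch}", params, history)
        history.append({"epoch": epoch, "loss_cls": l_cls, "loss_grl": l_grl, "loss": loss})
        opt_main.step(grads[:9])
        opt_disc.step(grads[9:])
    return params, history


def predict(params: GDAParams, target: DomainDataset) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax; ties -> lowest index) and posteriors for target cells."""
    Z_t, _ = gda_forward(target.S, target.S_P, target.X, params)
    post = classify(Z_t, params.W_cls, params.b_cls)
    return post.argmax(axis=1), post


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    accuracy: float
    macro_f1: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    confusion: np.ndarray | None = None
    classes: list[str] = field(default_factory=list)


def evaluate(predicted: np.ndarray, truth: np.ndarray, classes: list[str]) -> EvalReport:
    """Accuracy and macro-F1 over the source class set.

    Macro-F1 averages per-class F1 over ALL source classes; a class absent
    from both predictions and truth contributes F1 = 0 (explicit
    zero-division rule), keeping the metric comparable across runs.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    label_ids = np.arange(len(classes))
    if np.any(truth < 0) or np.any(truth >= len(classes)):
        raise ValueError("truth contains a class outside the source class set")
    acc = accuracy_score(truth, predicted)
    macro = f1_score(truth, predicted, labels=label_ids, average="macro", zero_division=0)
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, predicted, labels=label_ids, zero_division=0
    )
    per_class = {
        c: {"precision": float(prec[i]), "recall": float(rec[i]), "f1": float(f1[i])}
        for i, c in enumerate(classes)
    }
    cm = confusion_matrix(truth, predicted, labels=label_ids)
    return EvalReport(float(acc), float(macro), per_class, cm, list(classes))
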