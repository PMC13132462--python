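"""kNN cell graphs and their two propagation operators.

Each domain's cells become nodes of an exact k-nearest-neighbour graph built
on cosine similarity in the cell-embedding space (edges symmetrized by
union). Two operators are derived per graph:

* the self-loop-normalized adjacency  S = D~^{-1/2} (A + I) D~^{-1/2}
  driving the local-neighbourhood convolution channel, and
* a random-walk PPMI matrix driving the global channel: walk co-occurrence
  counts C(u, v) over walks of length L are turned into conditional
  probabilities P(v|u), marginals P(v) = sum_u P(v|u), and

      PPMI(u, v) = max(0, log( P(v|u)/P(v) * |V|/L ))

  with |V|/L a scalar normalization. Expected (closed-form) counts
  C(u, v) = w * sum_{t=1..L} (T^t)_{uv} over the row-normalized adjacency T
  are the deterministic default; Monte-Carlo walks are available and converge
  to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import pairwise_distances

from .cell_embedding import CellEmbeddingMatrix


@dataclass
class CellGraph:
    """An undirected kNN graph over one domain's cells with node features."""

    barcodes: list[str]
    adjacency: np.ndarray  # |V| x |V| binary, symmetric, zero diagonal
    features: np.ndarray  # |V| x d
    domain: str = ""
    k: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.barcodes):
            raise ValueError("adjacency must be square and aligned to barcodes")
        if np.any(A != A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class PPMIMatrix:
    """Nonnegative walk-association weights between cells (zero diagonal)."""

    values: np.ndarray
    walk_length: int
    mode: str  # monte_carlo | closed_form
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if np.any(v < 0) or np.any(np.diag(v) != 0) or not np.all(np.isfinite(v)):
            raise ValueError("PPMI must be finite, nonnegative, zero-diagonal")
        self.values = v


def build_knn_graph(
    embeddings: CellEmbeddingMatrix | np.ndarray,
    k: int = 6,
    metric: str = "cosine",
    barcodes: list[str] | None = None,
    domain: str = "",
) -> CellGraph:
    """Exact kNN graph: per node, edges to its k nearest neighbours (self excluded).

    Distance ties are broken toward the lower node index; the directed edge
    set is symmetrized by union.
    """
    if isinstance(embeddings, CellEmbeddingMatrix):
        X = embeddings.values
        barcodes = barcodes or embeddings.cell_barcodes
        domain = domain or embeddings.domain
    else:
        X = np.asarray(embeddings, dtype=np.float64)
        barcodes = barcodes or [f"cell{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"need 1 <= k < n_nodes, got k={k}, n={n}")
    if metric == "cosine" and np.any(np.linalg.norm(X, axis=1) == 0):
        raise ValueError("zero-norm embedding row: cosine distance undefined")
    D = pairwise_distances(X, metric=metric)
    np.fill_diagonal(D, np.inf)
    A = np.zeros((n, n), dtype=np.uint8)
    col_idx = np.arange(n)
    for i in range(n):
        nn = np.lexsort((col_idx, D[i]))[:k]  # distance first, then index
        A[i, nn] = 1
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0)
    return CellGraph(list(barcodes), A, X, domain, k)


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Self-loop symmetric normalization S = D~^{-1/2} (A + I) D~^{-1/2}."""
    A = np.asarray(A, dtype=np.float64)
    if np.any(A != A.T) or np.any(np.diag(A) != 0):
        raise ValueError("expected a symmetric zero-diagonal adjacency")
    At = A + np.eye(A.shape[0])
    dinv = 1.0 / np.sqrt(At.sum(axis=1))  # self-loops guarantee positive degrees
    return dinv[:, None] * At * dinv[None, :]


def walk_cooccurrence(
    graph: CellGraph | np.ndarray,
    walk_length: int = 3,
    walks_per_node: int = 1000,
    seed: int | None = None,
    mode: str = "closed_form",
) -> np.ndarray:
    """Visit counts C(u, v) from simple random walks started at every node.

    The start node's own visits are excluded (zero diagonal); repeat visits
    count. ``closed_form`` returns the exact expected counts
    ``walks_per_node * sum_t (T^t)_{uv}``; ``monte_carlo`` simulates walks
    (isolated nodes stay put and contribute an all-zero row).
    """
    A = graph.adjacency if isinstance(graph, CellGraph) else np.asarray(graph)
    A = A.astype(np.float64)
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    n = A.shape[0]
    deg = A.sum(axis=1)

    if mode == "closed_form":
        T = np.divide(A, deg[:, None], out=np.zeros_like(A), where=deg[:, None] > 0)
        C = np.zeros((n, n))
        M = np.eye(n)
        for _ in range(walk_length):
            M = M @ T
            C += M
        C *= walks_per_node
        np.fill_diagonal(C, 0.0)
        return C

    if mode != "monte_carlo":
        raise ValueError(f"unknown walk mode {mode!r}")
    rng = np.random.default_rng(seed)
    neighbors = [np.flatnonzero(A[i]) for i in range(n)]
    C = np.zeros((n, n))
    starts = np.repeat(np.arange(n), walks_per_node)
    current = starts.copy()
    movable = np.array([len(nb) > 0 for nb in neighbors])
    for _ in range(walk_length):
        nxt = current.copy()
        for i in np.flatnonzero(movable[current]):
            nb = neighbors[current[i]]
            nxt[i] = nb[rng.integers(len(nb))]
        current = nxt
        np.add.at(C, (starts, current), 1.0)
    np.fill_diagonal(C, 0.0)
    return C


def ppmi_from_counts(C: np.ndarray, n_nodes: int | None = None, walk_length: int = 3) -> PPMIMatrix:
    """Positive PMI from co-occurrence counts, normalized by |V|/L.

    Rows with no co-occurrences stay zero; pairs with zero conditional or
    marginal probability get weight 0 (the max(0, .) clamp keeps only
    positively associated pairs).
    """
    C = np.asarray(C, dtype=np.float64)
    if np.any(C < 0) or np.any(np.diag(C) != 0):
        raise ValueError("counts must be nonnegative with a zero diagonal")
    n = n_nodes if n_nodes is not None else C.shape[0]
    rowsum = C.sum(axis=1, keepdims=True)
    P_cond = np.divide(C, rowsum, out=np.zeros_like(C), where=rowsum > 0)
    P_marg = P_cond.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (P_cond > 0) & (P_marg[None, :] > 0),
            P_cond / np.where(P_marg[None, :] > 0, P_marg[None, :], 1.0),
            0.0,
        )
        ppmi = np.where(ratio > 0, np.log(ratio * (n / walk_length)), 0.0)
    ppmi = np.maximum(ppmi, 0.0)
    np.fill_diagonal(ppmi, 0.0)
    return PPMIMatrix(ppmi, walk_length, "closed_form")


def normalize_ppmi(P: PPMIMatrix | np.ndarray) -> np.ndarray:
    """Symmetrize PPMI weights and apply degree normalization D~^{-1/2} P D~^{-1/2}.

    Rows left with zero degree (cells with no positive association) receive a
    unit self-weight so the operator stays well defined; such nodes simply
    propagate their own features.
    """
    W = P.values if isinstance(P, PPMIMatrix) else np.asarray(P, dtype=np.float64)
    if np.any(W < 0):
        raise ValueError("PPMI weights must be nonnegative")
    W = (W + W.T) / 2.0
    deg = W.sum(axis=1)
    zero = deg == 0
    if np.any(zero):
        W = W.copy()
        W[zero, zero] = 1.0
        deg = W.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    return dinv[:, None] * W * dinv[None, :]


def ppmi_operator(
    graph: CellGraph,
    walk_length: int = 3,
    walks_per_node: int = 1000,
    mode: str = "closed_form",
    seed: int | None = None,
) -> np.ndarray:
    """Convenience chain: walks -> counts -> PPMI -> normalized operator."""
    C = walk_cooccurrence(graph, walk_length, walks_per_node, seed=seed, mode=mode)
    ppmi = ppmi_from_counts(C, graph.n_nodes, walk_length)
    return normalize_ppmi(ppmi)
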