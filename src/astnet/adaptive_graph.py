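"""Adaptive functional-connectivity generation.

Given one time-series window ``G = (x_1, ..., x_N)^T`` (rows are ROIs),
the adaptive graph-learning (AGL) rule builds a row-stochastic adjacency

    A_mn = exp(ReLU(w^T |x_m - x_n|)) / sum_n' exp(ReLU(w^T |x_m - x_n'|)),

with a single learnable weight vector ``w`` of length ``L`` shared across
windows and subjects.  A smoothness-plus-sparsity regularizer

    L_graph = sum_mn ||x_m - x_n||_2^2 A_mn + lambda ||A||_F^2

encourages larger weights between ROIs with similar signals.  The learned
``A`` drives a stack of graph-convolution layers ``H^{l+1} = sigma(A H^l
W^l)``, and the window's connectivity matrix is the second-order product
``S = H H^T`` of the final node features.  ``w = 0`` gives the degenerate
uniform graph ``A = 1/N``; it is avoided by training ``w`` jointly with
the classification loss rather than on the regularizer alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax_lastdim
from .nn import BatchNorm, Module, dropout, glorot_uniform

__all__ = [
    "AglParameters",
    "AdjacencyMatrix",
    "ConnectivityMatrix",
    "GcnStack",
    "adaptive_adjacency",
    "adjacency_tensor",
    "graph_learning_loss",
    "graph_loss_tensor",
    "gcn_forward",
    "connectivity_matrix",
    "connectivity_tensor",
    "vectorize_upper",
    "upper_triangle_tensor",
]


@dataclass
class AglParameters:
    """The learnable weight vector and regularization strength of AGL."""

    omega: np.ndarray
    lambda_reg: float = 1e-3

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=np.float64).reshape(-1)
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")


@dataclass
class AdjacencyMatrix:
    """Row-stochastic learned graph over ROIs (every entry > 0)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class ConnectivityMatrix:
    """Symmetric PSD second-order dependency matrix ``S = H H^T``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


# --------------------------------------------------------------- tensor cores
def adjacency_tensor(segments: Tensor, omega: Tensor) -> Tensor:
    """Batched AGL adjacency: ``(..., N, L) -> (..., N, N)``.

    Differentiable with respect to both the segments and ``omega``.
    """
    if segments.shape[-1] != omega.shape[-1]:
        raise ValueError(
            f"omega length {omega.shape[-1]} does not match window length "
            f"{segments.shape[-1]}"
        )
    # pairwise |x_m - x_n|: (..., N, 1, L) - (..., 1, N, L)
    diff = (segments.expand_dims(-2) - segments.expand_dims(-3)).abs()
    scores = (diff * omega).sum(axis=-1).relu()
    return softmax_lastdim(scores)


def graph_loss_tensor(segments: np.ndarray, adjacency: Tensor,
                      lambda_reg: float) -> Tensor:
    """Batched regularizer ``(..., N, L), (..., N, N) -> (...)``.

    The pairwise squared distances are data constants; the loss is
    differentiable through ``adjacency`` (hence through omega).
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")
    x = np.asarray(segments, dtype=np.float64)
    d2 = ((x[..., :, None, :] - x[..., None, :, :]) ** 2).sum(axis=-1)
    term1 = (adjacency * Tensor(d2)).sum(axis=(-1, -2))
    term2 = (adjacency * adjacency).sum(axis=(-1, -2)) * lambda_reg
    return term1 + term2


def connectivity_tensor(node_features: Tensor) -> Tensor:
    """Batched ``S = H H^T``: ``(..., N, D) -> (..., N, N)``."""
    return node_features @ node_features.swapaxes(-1, -2)


def upper_triangle_tensor(matrices: Tensor, n: int) -> Tensor:
    """Strict upper triangle of ``(..., N, N)`` in row-major order."""
    iu = np.triu_indices(n, k=1)
    flat_idx = iu[0] * n + iu[1]
    lead = matrices.shape[:-2]
    flat = matrices.reshape(lead + (n * n,))
    return flat[..., flat_idx]


# ---------------------------------------------------------- functional surface
def adaptive_adjacency(segment: np.ndarray, params: AglParameters) -> AdjacencyMatrix:
    """Learned adjacency of one window (row-softmax of ReLU(w^T |x_m - x_n|))."""
    segment = np.asarray(segment, dtype=np.float64)
    if not np.all(np.isfinite(segment)):
        raise ValueError("segment contains non-finite values")
    values = adjacency_tensor(Tensor(segment), Tensor(params.omega)).data
    return AdjacencyMatrix(values=values)


def graph_learning_loss(segment: np.ndarray, adjacency, lambda_reg: float) -> float:
    """Smoothness + Frobenius regularizer of one window's adjacency."""
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else adjacency
    a = np.asarray(a, dtype=np.float64)
    segment = np.asarray(segment, dtype=np.float64)
    if a.shape[0] != a.shape[1] or a.shape[0] != segment.shape[0]:
        raise ValueError("adjacency must be N x N matching the segment's N")
    return float(graph_loss_tensor(segment, Tensor(a), lambda_reg).data)


class GcnStack(Module):
    """Stack of graph-convolution layers ``H^{l+1} = sigma(A H^l W^l)``.

    Each layer is the linear graph aggregation followed (optionally) by
    batch normalization, then the activation, then dropout.  Dropout is
    active only in training mode; evaluation is deterministic.
    """

    def __init__(
        self,
        in_dim: int,
        hidden_dims: list[int] = (64, 64, 32),
        dropout_rate: float = 0.5,
        use_batch_norm: bool = True,
        activation: str = "relu",
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.hidden_dims = list(hidden_dims)
        self.dropout_rate = float(dropout_rate)
        self.use_batch_norm = bool(use_batch_norm)
        if activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")
        self.activation = activation
        dims = [in_dim] + self.hidden_dims
        self.layer_weights = [
            Tensor(glorot_uniform(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(len(self.hidden_dims))
        ]
        self.norms = (
            [BatchNorm(d) for d in self.hidden_dims] if self.use_batch_norm else []
        )

    @property
    def out_dim(self) -> int:
        return self.hidden_dims[-1]

    def forward(self, adjacency: Tensor, features: Tensor, training: bool,
                rng: np.random.Generator | None = None) -> Tensor:
        """Propagate ``(..., N, F)`` features through all layers.

        The same adjacency is reused by every layer of one window.
        """
        h = features
        for i, w in enumerate(self.layer_weights):
            if h.shape[-1] != w.shape[0]:
                raise ValueError(
                    f"GCN layer {i}: feature dim {h.shape[-1]} != weight rows "
                    f"{w.shape[0]}"
                )
            h = adjacency @ h @ w
            if self.use_batch_norm:
                h = self.norms[i](h, training)
            if self.activation == "relu":
                h = h.relu()
            if training and self.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                h = dropout(h, self.dropout_rate, rng, training)
        return h


def gcn_forward(segment: np.ndarray, adjacency, stack: GcnStack,
                training_mode: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Run one window through the GCN stack; returns final node features."""
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else adjacency
    h = stack.forward(
        Tensor(np.asarray(a, dtype=np.float64)),
        Tensor(np.asarray(segment, dtype=np.float64)),
        training=training_mode,
        rng=rng,
    )
    return h.data


def connectivity_matrix(node_features: np.ndarray) -> ConnectivityMatrix:
    """Second-order connectivity ``S = H H^T`` of final node features."""
    h = np.asarray(node_features, dtype=np.float64)
    if not np.all(np.isfinite(h)):
        raise ValueError("node features contain non-finite values")
    return ConnectivityMatrix(values=h @ h.T)


def vectorize_upper(matrix) -> np.ndarray:
    """Strict upper triangle (diagonal excluded) in row-major order.

    Length ``N (N - 1) / 2``; together with a zero diagonal this determines
    the symmetric matrix's off-diagonal part exactly.
    """
    m = matrix.values if isinstance(matrix, ConnectivityMatrix) else matrix
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]
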