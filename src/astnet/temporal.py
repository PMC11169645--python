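"""Temporal dependency mining over the window sequence.

Two parallel branches summarize the time-ordered connectivity vectors of a
subject:

* the **local branch** is a stacked bidirectional GRU over the window
  sequence — one GRU scans forward, the other backward, and their final
  hidden states are concatenated (a vector of length ``2 * units``);
* the **global branch** embeds each window's flattened connectivity with a
  three-layer MLP (widths 1024/256/32 by default), then applies channel
  attention across windows: the per-window features are average- and
  max-pooled over channels, both pooled descriptors pass through one
  shared two-layer MLP (bottleneck ``T / ratio``), their sum is squashed
  by a sigmoid into per-window weights in (0, 1), and the weighted sum of
  window features gives the 32-dimensional global output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import BiGRU, GRUCell, Linear, Module, dropout

__all__ = [
    "GruCellParameters",
    "WindowFeature",
    "AttentionWeights",
    "BranchOutputs",
    "WindowMlp",
    "ChannelAttention",
    "gru_step",
    "bigru_encode",
    "window_embed",
    "global_attention",
]


@dataclass
class GruCellParameters:
    """Weights of one GRU cell acting on ``[h_prev, x]`` (gates bias-free)."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    b_h: np.ndarray
    hidden_size: int

    def __post_init__(self) -> None:
        for name in ("W_z", "W_r", "W_h"):
            w = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, w)
            if w.ndim != 2 or w.shape[1] != self.hidden_size:
                raise ValueError(f"{name} must have shape (hidden+input, hidden)")
        self.b_h = np.asarray(self.b_h, dtype=np.float64).reshape(-1)
        if self.b_h.shape[0] != self.hidden_size:
            raise ValueError("b_h length must equal hidden_size")

    @property
    def input_dim(self) -> int:
        return self.W_z.shape[0] - self.hidden_size


def _cell_from_params(params: GruCellParameters) -> GRUCell:
    cell = GRUCell(params.input_dim, params.hidden_size, np.random.default_rng(0))
    cell.W_z.data = params.W_z.copy()
    cell.W_r.data = params.W_r.copy()
    cell.W_h.data = params.W_h.copy()
    cell.b_h.data = params.b_h.copy()
    return cell


def gru_step(x_t: np.ndarray, h_prev: np.ndarray,
             params: GruCellParameters) -> np.ndarray:
    """One deterministic GRU update ``h_prev, x_t -> h_t``."""
    x_t = np.asarray(x_t, dtype=np.float64).reshape(-1)
    h_prev = np.asarray(h_prev, dtype=np.float64).reshape(-1)
    if x_t.shape[0] != params.input_dim or h_prev.shape[0] != params.hidden_size:
        raise ValueError("input/hidden dimensions do not match the cell weights")
    cell = _cell_from_params(params)
    out = cell(Tensor(x_t[None, :]), Tensor(h_prev[None, :]))
    return out.data[0]


def bigru_encode(
    sequence,
    forward_params,
    backward_params,
    num_layers: int = 1,
) -> np.ndarray:
    """Encode a sequence of vectors with a stacked BiGRU.

    ``forward_params`` / ``backward_params`` are one
    :class:`GruCellParameters` per layer (a single instance is accepted
    when ``num_layers == 1``).  Returns the concatenation of the forward
    scan's final hidden state and the backward scan's final hidden state,
    a vector of length ``2 * units``.
    """
    seq = [np.asarray(v, dtype=np.float64).reshape(-1) for v in sequence]
    if len(seq) == 0:
        raise ValueError("empty sequence")
    fwd = [forward_params] if isinstance(forward_params, GruCellParameters) else list(forward_params)
    bwd = [backward_params] if isinstance(backward_params, GruCellParameters) else list(backward_params)
    if len(fwd) != num_layers or len(bwd) != num_layers:
        raise ValueError("need one parameter set per layer and direction")
    units = fwd[0].hidden_size
    net = BiGRU(fwd[0].input_dim, units, num_layers, np.random.default_rng(0))
    for layer, (f, b) in enumerate(zip(fwd, bwd)):
        cf, cb = net.layers[layer]
        for cell, p in ((cf, f), (cb, b)):
            cell.W_z.data = p.W_z.copy()
            cell.W_r.data = p.W_r.copy()
            cell.W_h.data = p.W_h.copy()
            cell.b_h.data = p.b_h.copy()
    out = net(Tensor(np.stack(seq)[None, :, :]))
    return out.data[0]


@dataclass
class WindowFeature:
    """Per-window embedded feature vector (length = final MLP width)."""

    values: np.ndarray


@dataclass
class AttentionWeights:
    """Per-window sigmoid attention weights, each strictly in (0, 1)."""

    values: np.ndarray


@dataclass
class BranchOutputs:
    """Fixed-length summaries of the two temporal branches."""

    local_feature: np.ndarray | None
    global_feature: np.ndarray | None


class WindowMlp(Module):
    """Three fully connected layers embedding one window's connectivity.

    ReLU after every layer; dropout after the first two (the two dropout
    layers of the reference configuration), active only in training mode.
    """

    def __init__(self, in_dim: int, dims=(1024, 256, 32),
                 dropout_rate: float = 0.5,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dims = list(dims)
        self.dropout_rate = float(dropout_rate)
        widths = [in_dim] + self.dims
        self.layers = [
            Linear(widths[i], widths[i + 1], rng) for i in range(len(self.dims))
        ]

    @property
    def out_dim(self) -> int:
        return self.dims[-1]

    def forward(self, x: Tensor, training: bool,
                rng: np.random.Generator | None = None) -> Tensor:
        h = x
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            h = layer(h).relu()
            if i < n - 1 and training and self.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                h = dropout(h, self.dropout_rate, rng, training)
        return h


def window_embed(flat_connectivity: np.ndarray, mlp: WindowMlp,
                 training_mode: bool = False,
                 rng: np.random.Generator | None = None) -> WindowFeature:
    """Embed one flattened connectivity vector; eval mode is deterministic."""
    v = np.asarray(flat_connectivity, dtype=np.float64).reshape(-1)
    out = mlp.forward(Tensor(v[None, :]), training=training_mode, rng=rng)
    return WindowFeature(values=out.data[0])


class ChannelAttention(Module):
    """Shared-MLP channel attention over the window axis.

    The bottleneck width is ``max(1, floor(T / ratio))`` so the mechanism
    is well defined down to very short sequences (T can be as small as 1).
    """

    def __init__(self, n_windows: int, reduction_ratio: int = 3,
                 rng: np.random.Generator | None = None):
        if n_windows < 1:
            raise ValueError("need at least one window")
        if reduction_ratio < 1:
            raise ValueError("reduction_ratio must be a positive integer")
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = max(1, n_windows // reduction_ratio)
        self.fc1 = Linear(n_windows, hidden, rng)
        self.fc2 = Linear(hidden, n_windows, rng)
        self.n_windows = n_windows

    def _shared_mlp(self, pooled: Tensor) -> Tensor:
        return self.fc2(self.fc1(pooled).relu())

    def forward(self, features: Tensor) -> tuple[Tensor, Tensor]:
        """``(B, T, F) -> (weighted sum (B, F), weights (B, T))``."""
        if features.shape[1] != self.n_windows:
            raise ValueError(
                f"expected {self.n_windows} windows, got {features.shape[1]}"
            )
        avg = features.mean(axis=-1)          # (B, T)
        mx = features.max(axis=-1)            # (B, T)
        weights = (self._shared_mlp(avg) + self._shared_mlp(mx)).sigmoid()
        pooled = (features * weights.expand_dims(-1)).sum(axis=1)
        return pooled, weights


def global_attention(
    features: np.ndarray, attention: ChannelAttention
) -> tuple[np.ndarray, AttentionWeights]:
    """Attention-pool a ``T x F`` feature stack into one length-F vector."""
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 2 or f.shape[0] < 1:
        raise ValueError("features must be a non-empty T x F matrix")
    pooled, weights = attention.forward(Tensor(f[None, :, :]))
    return pooled.data[0], AttentionWeights(values=weights.data[0])
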