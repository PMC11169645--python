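"""Neural-network layers and optimization on top of :mod:`astnet.autodiff`.

Layers hold their parameters as :class:`~astnet.autodiff.Tensor` objects
with ``requires_grad=True``; :meth:`Module.parameters` walks the module
tree to collect them for the optimizer.  Stochastic layers (dropout) draw
from an explicit :class:`numpy.random.Generator` so that training runs are
reproducible bit for bit given a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


class Module:
    """Base class: recursive parameter collection over attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj) -> None:
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        named: list[tuple[str, Tensor]] = []
        seen: set[int] = set()

        def collect(obj, prefix: str) -> None:
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    named.append((prefix, obj))
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    collect(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    collect(v, f"{prefix}[{i}]")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    collect(v, f"{prefix}[{k}]")

        collect(self, "")
        return named

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter in checkpoint: {name}")
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Linear(Module):
    """Affine map on the last axis: ``y = x @ W + b``."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Tensor(glorot_uniform(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x) -> Tensor:
        y = _as_tensor(x) @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class BatchNorm(Module):
    """Normalization of the last (channel) axis over all other axes.

    Training mode uses batch statistics and updates exponential running
    averages; evaluation mode uses the running averages, so evaluation is
    deterministic and independent of batch composition.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x, training: bool) -> Tensor:
        x = _as_tensor(x)
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class GRUCell(Module):
    """Gated recurrent unit acting on the concatenation ``[h_prev, x]``.

    Gates: ``z = sigmoid([h, x] W_z)``, ``r = sigmoid([h, x] W_r)``,
    candidate ``h~ = tanh([r * h, x] W_h + b_h)``, update
    ``h' = (1 - z) * h + z * h~``.  Gate weights carry no bias; only the
    candidate has ``b_h``.
    """

    def __init__(self, input_dim: int, hidden_size: int,
                 rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden_size)
        shape = (hidden_size + input_dim, hidden_size)
        self.W_z = Tensor(rng.uniform(-k, k, shape), requires_grad=True)
        self.W_r = Tensor(rng.uniform(-k, k, shape), requires_grad=True)
        self.W_h = Tensor(rng.uniform(-k, k, shape), requires_grad=True)
        self.b_h = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.input_dim = input_dim
        self.hidden_size = hidden_size

    def __call__(self, x, h_prev) -> Tensor:
        x, h_prev = _as_tensor(x), _as_tensor(h_prev)
        hx = concat([h_prev, x], axis=-1)
        z = (hx @ self.W_z).sigmoid()
        r = (hx @ self.W_r).sigmoid()
        cand = concat([r * h_prev, x], axis=-1) @ self.W_h + self.b_h
        h_tilde = cand.tanh()
        return (1.0 - z) * h_prev + z * h_tilde


class BiGRU(Module):
    """Stacked bidirectional GRU; returns the final states of both scans.

    Each layer runs one GRU forward over the sequence and one backward;
    layer ``l > 0`` consumes the per-step concatenation of both direction
    outputs of layer ``l - 1``.  The output is ``h_fwd_final (+) h_bwd_final``
    of the top layer, a vector of length ``2 * units``.
    """

    def __init__(self, input_dim: int, units: int, num_layers: int,
                 rng: np.random.Generator):
        self.layers: list[tuple[GRUCell, GRUCell]] = []
        for layer in range(num_layers):
            d = input_dim if layer == 0 else 2 * units
            self.layers.append((GRUCell(d, units, rng), GRUCell(d, units, rng)))
        self.units = units

    def __call__(self, seq: Tensor) -> Tensor:
        """seq: (B, T, D) -> (B, 2 * units)."""
        seq = _as_tensor(seq)
        if seq.shape[1] < 1:
            raise ValueError("empty sequence")
        B, T = seq.shape[0], seq.shape[1]
        h_f = h_b = None
        for fwd, bwd in self.layers:
            h_f = Tensor(np.zeros((B, self.units)))
            h_b = Tensor(np.zeros((B, self.units)))
            outs_f: list[Tensor] = []
            outs_b: list[Tensor] = [None] * T  # type: ignore[list-item]
            for t in range(T):
                h_f = fwd(seq[:, t, :], h_f)
                outs_f.append(h_f)
            for t in range(T - 1, -1, -1):
                h_b = bwd(seq[:, t, :], h_b)
                outs_b[t] = h_b
            from .autodiff import stack as _stack

            seq = concat(
                [_stack(outs_f, axis=1), _stack(outs_b, axis=1)], axis=-1
            )
        return concat([h_f, h_b], axis=-1)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]
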