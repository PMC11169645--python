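"""End-to-end model assembly: adaptive graphs -> GCN -> temporal mining.

The full dynamic model processes one subject as follows.  The ROI series
is cut into ``T`` non-overlapping windows of length ``L``.  Per window, an
adjacency is learned by the AGL rule (one shared weight vector ``omega``),
propagated through a three-layer GCN, and the final node features are
turned into a connectivity matrix ``S_t = H H^T`` whose strict upper
triangle is the window's feature vector.  A global branch embeds each
window vector with a three-layer MLP and attention-pools across windows;
a local branch runs a stacked BiGRU over the window vectors.  Branch
outputs are concatenated and classified by a three-layer fully connected
head.  The training objective is cross-entropy plus the graph-learning
regularizer.

Ablation and baseline variants share the exact submodules with one
component removed or replaced (Pearson adjacency instead of AGL, no GCN,
single full-length window, single branch); see :data:`VARIANTS`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .adaptive_graph import (
    GcnStack,
    adjacency_tensor,
    connectivity_tensor,
    graph_loss_tensor,
    upper_triangle_tensor,
)
from .autodiff import Tensor, concat, log_softmax_lastdim, softmax_lastdim
from .nn import BatchNorm, BiGRU, Linear, Module, dropout
from .temporal import ChannelAttention, WindowMlp
from .windowing import SegmentSet

__all__ = ["ModelConfig", "ASTNet", "build_variant", "total_loss", "VARIANTS",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setup)."""

    window_length: int = 20
    n_rois: int = 116
    gcn_dims: tuple = (64, 64, 32)
    mlp_dims: tuple = (1024, 256, 32)
    gru_units: int = 4
    gru_layers: int = 2
    attention_ratio: int = 3
    dropout: float = 0.5
    lambda_reg: float = 1e-3
    head_dims: tuple = (32, 16, 2)
    seed: int = 0
    # package choices: GRU input projection width and the weight of
    # the graph regularizer in the joint loss (1.0 = plain additive sum).
    gru_input_dim: int = 64
    graph_loss_coef: float = 1.0
    use_batch_norm: bool = True
    omega_init_std: float = 0.1
    # z-score each window's flattened connectivity vector before the
    # temporal branches; raw S_t = H H^T entries grow with the GCN width,
    # and standardizing them keeps the MLP/GRU inputs well conditioned
    feature_norm: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gcn_dims"] = list(self.gcn_dims)
        d["mlp_dims"] = list(self.mlp_dims)
        d["head_dims"] = list(self.head_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("gcn_dims", "mlp_dims", "head_dims"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# variant name -> architectural flags
VARIANTS: dict[str, dict] = {
    # full model: adaptive graphs, GCN, both temporal branches
    "ASTNet": dict(static=False, adjacency="agl", gcn=True, feat="gcn",
                   local=True, global_=True),
    # without the global attention branch
    "ASTNet_G": dict(static=False, adjacency="agl", gcn=True, feat="gcn",
                     local=True, global_=False),
    # without the local BiGRU branch
    "ASTNet_L": dict(static=False, adjacency="agl", gcn=True, feat="gcn",
                     local=False, global_=True),
    # Pearson-correlation adjacency instead of AGL (clean graph ablation)
    "GCN_d": dict(static=False, adjacency="pearson", gcn=True, feat="gcn",
                  local=True, global_=True),
    # adaptive graphs without GCN: the symmetrized adjacency is the feature
    "AGL_d": dict(static=False, adjacency="agl", gcn=False, feat="adjacency",
                  local=True, global_=True),
    # static (single full-length window) counterparts
    "GCN_s": dict(static=True, adjacency="pearson", gcn=True, feat="gcn",
                  local=False, global_=False),
    "AGL_s": dict(static=True, adjacency="agl", gcn=False, feat="adjacency",
                  local=False, global_=False),
    "MLP_s": dict(static=True, adjacency=None, gcn=False, feat="pearson_fc",
                  local=False, global_=False),
    # windowed Pearson FC baselines
    "MLP_d": dict(static=False, adjacency=None, gcn=False, feat="pearson_fc",
                  local=False, global_=True),
    "BiGRU": dict(static=False, adjacency=None, gcn=False, feat="pearson_fc",
                  local=True, global_=False),
}


def _windowed_pearson(windows: np.ndarray) -> np.ndarray:
    """Pearson correlation per window: ``(B, T, N, L) -> (B, T, N, N)``.

    Zero-variance rows get zero correlation with everything (diagonal 1).
    """
    xc = windows - windows.mean(axis=-1, keepdims=True)
    cov = np.einsum("btnl,btml->btnm", xc, xc)
    ss = np.einsum("btnl,btnl->btn", xc, xc)
    sd = np.sqrt(ss)
    denom = sd[..., :, None] * sd[..., None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    n = corr.shape[-1]
    corr[..., np.arange(n), np.arange(n)] = 1.0
    return corr


class ASTNet(Module):
    """Adaptive spatial-temporal network (and its ablation variants)."""

    def __init__(self, config: ModelConfig, n_timepoints: int,
                 variant: str = "ASTNet"):
        if variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {variant!r}; valid names: "
                + ", ".join(sorted(VARIANTS))
            )
        self.config = config
        self.variant = variant
        self.flags = VARIANTS[variant]
        self.n_rois = config.n_rois
        self.n_timepoints = int(n_timepoints)
        if self.flags["static"]:
            self.window_length = self.n_timepoints
            self.n_windows = 1
        else:
            self.window_length = config.window_length
            self.n_windows = self.n_timepoints // config.window_length
            if self.n_windows < 1:
                raise ValueError("series shorter than one window")

        n = self.n_rois
        self.n_edge_features = n * (n - 1) // 2

        ss = np.random.SeedSequence(config.seed)
        init_rng, drop_rng = (np.random.default_rng(c) for c in ss.spawn(2))
        self._dropout_rng = drop_rng

        # adaptive graph-learning weight (shared across windows and subjects)
        if self.flags["adjacency"] == "agl":
            self.omega = Tensor(
                init_rng.normal(0.0, config.omega_init_std, self.window_length),
                requires_grad=True,
            )
        else:
            self.omega = None

        if self.flags["gcn"]:
            self.gcn = GcnStack(
                in_dim=self.window_length,
                hidden_dims=list(config.gcn_dims),
                dropout_rate=config.dropout,
                use_batch_norm=config.use_batch_norm,
                rng=init_rng,
            )
        else:
            self.gcn = None

        # global branch (the per-window MLP belongs to it), or the static MLP
        self.mlp = None
        self.attention = None
        if self.flags["global_"] or self.flags["static"]:
            self.mlp = WindowMlp(
                self.n_edge_features, dims=list(config.mlp_dims),
                dropout_rate=config.dropout, rng=init_rng,
            )
        if self.flags["global_"]:
            self.attention = ChannelAttention(
                self.n_windows, reduction_ratio=config.attention_ratio,
                rng=init_rng,
            )

        # local branch: shared linear projection then stacked BiGRU
        self.local_proj = None
        self.bigru = None
        if self.flags["local"]:
            self.local_proj = Linear(self.n_edge_features,
                                     config.gru_input_dim, init_rng)
            self.bigru = BiGRU(config.gru_input_dim, config.gru_units,
                               config.gru_layers, init_rng)

        # classification head
        if self.flags["static"]:
            self.head = [Linear(self.mlp.out_dim, 2, init_rng)]
        else:
            head_in = 0
            if self.flags["global_"]:
                head_in += self.mlp.out_dim
            if self.flags["local"]:
                head_in += 2 * config.gru_units
            widths = [head_in] + list(config.head_dims)
            self.head = [
                Linear(widths[i], widths[i + 1], init_rng)
                for i in range(len(widths) - 1)
            ]

    # ------------------------------------------------------------------ utils
    @property
    def uses_graph_loss(self) -> bool:
        return self.flags["adjacency"] == "agl"

    def _partition(self, data: np.ndarray) -> np.ndarray:
        """(B, N, T_total) -> (B, T, N, L), trailing remainder dropped."""
        b, n, total = data.shape
        t, length = self.n_windows, self.window_length
        if total < length:
            raise ValueError("series shorter than one window")
        trimmed = data[:, :, : t * length]
        return np.ascontiguousarray(
            trimmed.reshape(b, n, t, length).transpose(0, 2, 1, 3)
        )

    # ---------------------------------------------------------------- forward
    def forward_batch(
        self, data: np.ndarray, training: bool = False
    ) -> tuple[Tensor, Tensor, dict]:
        """Run a batch ``(B, n_rois, n_timepoints)`` through the pipeline.

        Returns (logits ``(B, 2)``, mean per-subject graph loss, diagnostics
        with per-window adjacencies / connectivity matrices / attention
        weights as plain arrays).
        """
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 3 or data.shape[1] != self.n_rois:
            raise ValueError(
                f"expected (B, {self.n_rois}, T) input, got {data.shape}"
            )
        windows = self._partition(data)  # (B, T, N, L)
        rng = self._dropout_rng
        diagnostics: dict = {}

        adjacency = None
        graph_loss = Tensor(0.0)
        if self.flags["adjacency"] == "agl":
            adjacency = adjacency_tensor(Tensor(windows), self.omega)
            per_window = graph_loss_tensor(windows, adjacency,
                                           self.config.lambda_reg)
            graph_loss = per_window.sum(axis=1).mean()
        elif self.flags["adjacency"] == "pearson":
            corr = np.abs(_windowed_pearson(windows))
            adjacency = softmax_lastdim(Tensor(corr))
        if adjacency is not None:
            diagnostics["adjacency"] = adjacency.data.copy()

        feat = self.flags["feat"]
        if feat == "gcn":
            h = self.gcn.forward(adjacency, Tensor(windows), training, rng)
            connectivity = connectivity_tensor(h)
            vectors = upper_triangle_tensor(connectivity, self.n_rois)
            diagnostics["connectivity"] = connectivity.data.copy()
        elif feat == "adjacency":
            sym = (adjacency + adjacency.swapaxes(-1, -2)) * 0.5
            vectors = upper_triangle_tensor(sym, self.n_rois)
            diagnostics["connectivity"] = sym.data.copy()
        elif feat == "pearson_fc":
            corr = _windowed_pearson(windows)
            vectors = upper_triangle_tensor(Tensor(corr), self.n_rois)
            diagnostics["connectivity"] = corr.copy()
        else:  # pragma: no cover - exhaustive over VARIANTS
            raise AssertionError(feat)

        if self.config.feature_norm and feat != "pearson_fc":
            # Pearson features are already on a bounded, comparable scale
            mu = vectors.mean(axis=-1, keepdims=True)
            var = ((vectors - mu) ** 2.0).mean(axis=-1, keepdims=True)
            vectors = (vectors - mu) * ((var + 1e-8) ** -0.5)

        if self.flags["static"]:
            emb = self.mlp.forward(vectors, training, rng)  # (B, 1, 32)
            z = emb.reshape(emb.shape[0], emb.shape[2])
            logits = self.head[0](z)
            return logits, graph_loss, diagnostics

        branches: list[Tensor] = []
        if self.flags["global_"]:
            features = self.mlp.forward(vectors, training, rng)  # (B, T, 32)
            pooled, weights = self.attention.forward(features)
            branches.append(pooled)
            diagnostics["attention"] = weights.data.copy()
        if self.flags["local"]:
            seq = self.local_proj(vectors)  # (B, T, gru_input_dim)
            branches.append(self.bigru(seq))
        z = branches[0] if len(branches) == 1 else concat(branches, axis=-1)
        for i, layer in enumerate(self.head):
            z = layer(z)
            if i < len(self.head) - 1:
                z = z.relu()
                if training and self.config.dropout > 0:
                    z = dropout(z, self.config.dropout, rng, training)
        return z, graph_loss, diagnostics

    def forward(
        self, segments: SegmentSet, training: bool = False
    ) -> tuple[np.ndarray, float, dict]:
        """Single-subject forward from a :class:`SegmentSet`."""
        mats = segments.segments
        if len(mats) != self.n_windows:
            raise ValueError(
                f"model built for T={self.n_windows} windows, got {len(mats)}"
            )
        for m in mats:
            if m.shape != (self.n_rois, self.window_length):
                raise ValueError("inconsistent segment shapes")
        data = np.concatenate(mats, axis=1)[None, :, :]
        logits, graph_loss, diagnostics = self.forward_batch(data, training)
        diagnostics = {k: v[0] for k, v in diagnostics.items()}
        return logits.data[0], float(graph_loss.data), diagnostics

    # ------------------------------------------------------------ batch norm
    def _batch_norms(self) -> list[BatchNorm]:
        norms: list[BatchNorm] = []

        def walk(obj) -> None:
            if isinstance(obj, BatchNorm):
                norms.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return norms


def batch_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of ``(B, 2)`` logits against integer labels."""
    labels = np.asarray(labels)
    logp = log_softmax_lastdim(logits)
    picked = logp[(np.arange(labels.shape[0]), labels)]
    return -picked.mean()


def total_loss(class_logits, label: int, graph_loss: float,
               coefficient: float = 1.0) -> float:
    """Joint objective of one subject: cross-entropy + graph regularizer."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    logits = class_logits.data if isinstance(class_logits, Tensor) else class_logits
    logits = np.asarray(logits, dtype=np.float64).reshape(-1)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    shifted = logits - logits.max()
    logp = shifted - np.log(np.exp(shifted).sum())
    return float(-logp[label] + coefficient * float(graph_loss))


def build_variant(name: str, config: ModelConfig, n_timepoints: int) -> ASTNet:
    """Instantiate the named model variant (see :data:`VARIANTS`)."""
    return ASTNet(config, n_timepoints=n_timepoints, variant=name)


# ------------------------------------------------------------- checkpointing
def save_checkpoint(model: ASTNet, path: str | Path, *, optimizer=None,
                    epoch: int = 0, extra: dict | None = None) -> None:
    """Serialize parameters (+ batch-norm stats, optimizer state) to .npz.

    A JSON sidecar ``<path>.json`` records the config, variant, series
    length and epoch so the model can be rebuilt exactly.
    """
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for name, p in model.named_parameters():
        arrays["param/" + name] = p.data
    for i, bn in enumerate(model._batch_norms()):
        arrays[f"bn/{i}/mean"] = bn.running_mean
        arrays[f"bn/{i}/var"] = bn.running_var
    if optimizer is not None:
        arrays["opt/t"] = np.asarray(optimizer.t)
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            arrays[f"opt/m/{i}"] = m
            arrays[f"opt/v/{i}"] = v
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)  # write to handle: no implicit .npz suffix
    sidecar = {
        "config": model.config.to_dict(),
        "variant": model.variant,
        "n_timepoints": model.n_timepoints,
        "epoch": int(epoch),
    }
    if extra:
        sidecar.update(extra)
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str | Path):
    """Rebuild a model (and optimizer state, epoch) from a checkpoint."""
    path = Path(path)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    config = ModelConfig.from_dict(sidecar["config"])
    model = ASTNet(config, n_timepoints=sidecar["n_timepoints"],
                   variant=sidecar["variant"])
    with np.load(path) as arch:
        data = {k: arch[k] for k in arch.files}
    model.load_state_dict(
        {k[len("param/"):]: v for k, v in data.items() if k.startswith("param/")}
    )
    for i, bn in enumerate(model._batch_norms()):
        bn.running_mean = data[f"bn/{i}/mean"].copy()
        bn.running_var = data[f"bn/{i}/var"].copy()
    opt_state = None
    if "opt/t" in data:
        n = len(model.parameters())
        opt_state = {
            "t": int(data["opt/t"]),
            "m": [data[f"opt/m/{i}"] for i in range(n)],
            "v": [data[f"opt/v/{i}"] for i in range(n)],
        }
    return model, opt_state, int(sidecar.get("epoch", 0))
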