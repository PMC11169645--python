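"""Training loop, classification metrics, and group-difference analysis.

Metrics follow the clinical convention with patients (label 1) as the
positive class: ACC = (TP+TN)/(TP+TN+FP+FN), SEN = TP/(TP+FN),
SPE = TN/(TN+FP), all reported in percent.  Group-difference maps apply an
edge-wise two-sample Welch t-test to per-window connectivity values across
subjects and binarize the p-values at 0.05 (1 where p > 0.05, 0 where the
edge differs significantly); a full-series Pearson map serves as the
static comparator.  No multiple-testing correction is applied by default;
an FDR option exists for users who want it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .model import ASTNet, batch_cross_entropy
from .nn import Adam
from .windowing import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "EvalMetrics",
    "GroupDifferenceMap",
    "TrainSettings",
    "train",
    "evaluate",
    "predict",
    "group_difference_maps",
    "window_sweep",
    "stratified_split",
]


@dataclass
class EvalMetrics:
    """Confusion counts and the percent metrics derived from them."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float = field(init=False)
    sen: float = field(init=False)
    spe: float = field(init=False)

    def __post_init__(self) -> None:
        self.acc = self._ratio(self.tp + self.tn,
                               self.tp + self.tn + self.fp + self.fn, "ACC")
        self.sen = self._ratio(self.tp, self.tp + self.fn, "SEN")
        self.spe = self._ratio(self.tn, self.tn + self.fp, "SPE")

    @staticmethod
    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                          stacklevel=3)
            return float("nan")
        return 100.0 * num / den

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "EvalMetrics":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class GroupDifferenceMap:
    """Edge-wise p-values and their 0.05-binarized map for one segment."""

    p_values: np.ndarray
    binarized: np.ndarray
    segment_index: int  # -1 marks the static (full-series) comparator


@dataclass
class TrainSettings:
    """Optimization protocol (Adam on the joint loss, plateau stopping)."""

    lr: float = 1e-3
    weight_decay: float = 0.0
    max_epochs: int = 200
    batch_size: int = 16
    patience: int = 20
    min_delta: float = 1e-4
    seed: int = 0


def _cohort_arrays(cohort: list[RoiTimeSeries]) -> tuple[np.ndarray, np.ndarray]:
    if not cohort:
        raise ValueError("empty cohort")
    lengths = {s.n_timepoints for s in cohort}
    n_rois = {s.n_rois for s in cohort}
    if len(lengths) != 1 or len(n_rois) != 1:
        raise ValueError("all subjects must share n_rois and series length")
    data = np.stack([s.data for s in cohort])
    labels = np.array([s.label for s in cohort], dtype=int)
    return data, labels


def stratified_split(cohort: list[RoiTimeSeries], test_fraction: float = 0.3,
                     seed: int = 0):
    """Label-stratified train/test split of a cohort."""
    labels = [s.label for s in cohort]
    train_set, test_set = train_test_split(
        cohort, test_size=test_fraction, stratify=labels,
        random_state=int(seed) % (2**31), shuffle=True,
    )
    return train_set, test_set


def train(model: ASTNet, cohort: list[RoiTimeSeries],
          settings: TrainSettings | None = None,
          history_path=None, resume_state: dict | None = None) -> pd.DataFrame:
    """Fit a model on a cohort; returns the per-epoch loss history.

    Seeded and deterministic: the same model seed plus the same
    ``settings.seed`` reproduce the history exactly.  Early stopping
    triggers after ``patience`` epochs without a ``min_delta`` improvement
    of the total loss.
    """
    settings = settings or TrainSettings()
    data, labels = _cohort_arrays(cohort)
    if len(np.unique(labels)) < 2:
        raise ValueError("cohort must contain both classes")
    rng = np.random.default_rng(settings.seed)
    optimizer = Adam(model.parameters(), lr=settings.lr,
                     weight_decay=settings.weight_decay)
    if resume_state is not None:
        optimizer.load_state(resume_state)
    n = data.shape[0]
    coef = model.config.graph_loss_coef
    history: list[dict] = []
    best = np.inf
    stale = 0
    for epoch in range(settings.max_epochs):
        order = rng.permutation(n)
        tot_sum = ce_sum = gl_sum = 0.0
        correct = 0
        for start in range(0, n, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            logits, graph_loss, _ = model.forward_batch(data[idx], training=True)
            ce = batch_cross_entropy(logits, labels[idx])
            total = ce + coef * graph_loss if model.uses_graph_loss else ce
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            b = len(idx)
            tot_sum += float(total.data) * b
            ce_sum += float(ce.data) * b
            gl_sum += float(graph_loss.data) * b
            correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
        row = {
            "epoch": epoch,
            "total_loss": tot_sum / n,
            "cross_entropy": ce_sum / n,
            "graph_loss": gl_sum / n,
            "train_acc": 100.0 * correct / n,
        }
        history.append(row)
        if row["total_loss"] < best - settings.min_delta:
            best = row["total_loss"]
            stale = 0
        else:
            stale += 1
            if stale >= settings.patience:
                logger.info("early stop at epoch %d (plateau)", epoch)
                break
    frame = pd.DataFrame(history)
    if history_path is not None:
        frame.to_csv(history_path, index=False)
    return frame


def predict(model: ASTNet, cohort: list[RoiTimeSeries],
            batch_size: int = 32) -> np.ndarray:
    """Deterministic eval-mode logits for every subject, shape (B, 2)."""
    data, _ = _cohort_arrays(cohort)
    chunks = []
    for start in range(0, data.shape[0], batch_size):
        logits, _, _ = model.forward_batch(data[start:start + batch_size],
                                           training=False)
        chunks.append(logits.data)
    return np.concatenate(chunks, axis=0)


def evaluate(model: ASTNet, cohort: list[RoiTimeSeries]) -> EvalMetrics:
    """Confusion-count metrics of argmax predictions on a labeled cohort."""
    _, labels = _cohort_arrays(cohort)
    preds = predict(model, cohort).argmax(axis=1)
    return EvalMetrics.from_predictions(labels, preds)


def _model_connectivity(model: ASTNet, cohort: list[RoiTimeSeries],
                        batch_size: int = 32) -> np.ndarray:
    """Per-window learned connectivity S_t, shape (B, T, N, N), symmetrized."""
    data, _ = _cohort_arrays(cohort)
    chunks = []
    for start in range(0, data.shape[0], batch_size):
        _, _, diag = model.forward_batch(data[start:start + batch_size],
                                         training=False)
        if "connectivity" not in diag:
            raise ValueError(
                f"variant {model.variant} exposes no connectivity diagnostics"
            )
        s = diag["connectivity"]
        chunks.append((s + np.swapaxes(s, -1, -2)) / 2.0)
    return np.concatenate(chunks, axis=0)


def _windowed_pearson_cohort(cohort: list[RoiTimeSeries],
                             window_length: int) -> np.ndarray:
    from .model import _windowed_pearson

    data, _ = _cohort_arrays(cohort)
    b, n, total = data.shape
    t = total // window_length
    windows = data[:, :, : t * window_length].reshape(
        b, n, t, window_length
    ).transpose(0, 2, 1, 3)
    return _windowed_pearson(windows)


def group_difference_maps(
    cohort: list[RoiTimeSeries],
    model: ASTNet | None = None,
    source: str = "model",
    window_length: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> tuple[list[GroupDifferenceMap], GroupDifferenceMap]:
    """Edge-wise Welch t-test maps per segment, plus a static comparator.

    ``source='model'`` tests the trained model's learned per-window
    connectivity matrices S_t; ``source='pearson'`` tests windowed Pearson
    FC and needs no model.  The binarized maps put 1 where p > alpha
    (no detected difference) and 0 where the edge differs.  ``fdr=True``
    applies Benjamini-Hochberg within each segment before binarizing
    (off by default; the plain per-edge rule is the reference behavior).
    """
    _, labels = _cohort_arrays(cohort)
    if min(np.sum(labels == 0), np.sum(labels == 1)) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if source == "model":
        if model is None:
            raise ValueError("source='model' requires a fitted model")
        fc = _model_connectivity(model, cohort)
        window_length = model.window_length
    elif source == "pearson":
        if window_length is None:
            raise ValueError("source='pearson' requires window_length")
        fc = _windowed_pearson_cohort(cohort, window_length)
    else:
        raise ValueError("source must be 'model' or 'pearson'")

    def _maps(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            result = stats.ttest_ind(values_a, values_b, axis=0,
                                     equal_var=False)
        p = np.asarray(result.pvalue)
        return np.where(np.isfinite(p), p, 1.0)  # constant edges: no evidence

    def _binarize(p: np.ndarray) -> np.ndarray:
        if fdr:
            flat = p[np.triu_indices(p.shape[0], k=1)]
            reject = _bh_reject(flat, alpha)
            out = np.ones_like(p, dtype=int)
            iu = np.triu_indices(p.shape[0], k=1)
            out[iu] = (~reject).astype(int)
            out = np.minimum(out, out.T)
            np.fill_diagonal(out, 1)
            return out
        return (p > alpha).astype(int)

    a, b = fc[labels == 0], fc[labels == 1]
    maps = []
    for t in range(fc.shape[1]):
        p = _maps(a[:, t], b[:, t])
        maps.append(GroupDifferenceMap(p_values=p, binarized=_binarize(p),
                                       segment_index=t))
    # static comparator: full-series Pearson FC
    data, _ = _cohort_arrays(cohort)
    from .model import _windowed_pearson
    static_fc = _windowed_pearson(data[:, None, :, :])[:, 0]
    p_static = _maps(static_fc[labels == 0], static_fc[labels == 1])
    static_map = GroupDifferenceMap(p_values=p_static,
                                    binarized=_binarize(p_static),
                                    segment_index=-1)
    return maps, static_map


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask for a flat vector of p-values."""
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def window_sweep(
    cohort: list[RoiTimeSeries],
    window_lengths,
    config,
    settings: TrainSettings | None = None,
    variant: str = "ASTNet",
    test_fraction: float = 0.3,
    out_csv=None,
) -> pd.DataFrame:
    """Re-partition, retrain and evaluate for each candidate window length.

    Lengths longer than the shortest series are recorded as skipped rather
    than failing the sweep.  One row per non-skipped length.
    """
    import dataclasses as _dc

    from .model import build_variant

    settings = settings or TrainSettings()
    data, _ = _cohort_arrays(cohort)
    min_len = data.shape[2]
    rows = []
    for length in window_lengths:
        if length < 1 or length > min_len:
            logger.warning("skipping window length %s (series length %d)",
                           length, min_len)
            continue
        cfg = _dc.replace(config, window_length=int(length))
        train_set, test_set = stratified_split(cohort, test_fraction,
                                               seed=settings.seed)
        model = build_variant(variant, cfg, n_timepoints=min_len)
        train(model, train_set, settings)
        metrics = evaluate(model, test_set)
        rows.append({
            "window_length": int(length),
            "n_segments": model.n_windows,
            "acc": metrics.acc, "sen": metrics.sen, "spe": metrics.spe,
        })
    frame = pd.DataFrame(rows)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame
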