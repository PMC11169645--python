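"""Loading and windowing of ROI time series.

A subject is an ``N_rois x T_total`` real matrix of region-averaged BOLD
signals plus a binary diagnostic label (1 = patient, 0 = control).  The
first stage of the pipeline partitions each series into ``T = floor(T_total
/ L)`` contiguous, non-overlapping windows of fixed length ``L``; any
trailing remainder of fewer than ``L`` timepoints is discarded (and
logged).  With the default ``L = 20``, typical acquisition lengths of
231, 171, 72, 256 and 119 timepoints give 11, 8, 3, 12 and 5 windows
respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RoiTimeSeries",
    "SegmentSet",
    "partition",
    "partition_matrix",
    "load_subject",
    "load_cohort",
]


@dataclass
class RoiTimeSeries:
    """One subject's ROI x time signal matrix with its diagnostic label."""

    subject_id: str
    data: np.ndarray  # (n_rois, n_timepoints)
    label: int
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_rois, n_timepoints) matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 ROIs")
        if self.data.shape[1] < 1:
            raise ValueError("need at least 1 timepoint")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in series {self.subject_id!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class SegmentSet:
    """The ordered non-overlapping windows of one subject."""

    segments: list[np.ndarray] = field(repr=False)
    window_length: int
    origin: str

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def partition_matrix(data: np.ndarray, window_length: int) -> np.ndarray:
    """Split ``(n_rois, T_total)`` into a ``(T, n_rois, L)`` stack.

    Pure array form used by the models; see :func:`partition` for the
    subject-level wrapper and the contract.
    """
    if window_length <= 0:
        raise ValueError("window_length must be a positive integer")
    n_rois, total = data.shape
    if total < window_length:
        raise ValueError("series shorter than one window")
    t = total // window_length
    trimmed = data[:, : t * window_length]
    # (N, T*L) -> (N, T, L) -> (T, N, L)
    return np.ascontiguousarray(
        trimmed.reshape(n_rois, t, window_length).transpose(1, 0, 2)
    )


def partition(series: RoiTimeSeries, window_length: int) -> SegmentSet:
    """Partition a subject's series into ``floor(T_total / L)`` windows.

    Windows are contiguous, non-overlapping and in temporal order;
    concatenating them column-wise reproduces the first ``T * L`` columns
    of the input exactly.  The input is not modified.
    """
    stack_ = partition_matrix(series.data, window_length)
    dropped = series.n_timepoints - stack_.shape[0] * window_length
    if dropped:
        logger.info(
            "subject %s: discarding %d trailing timepoint(s) (T_total=%d, L=%d)",
            series.subject_id, dropped, series.n_timepoints, window_length,
        )
    return SegmentSet(
        segments=[stack_[t].copy() for t in range(stack_.shape[0])],
        window_length=window_length,
        origin=series.subject_id,
    )


def _read_matrix(path: Path) -> np.ndarray:
    """Read one delimited-text matrix (TSV or CSV, no header)."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    # round_trip parser: text written with 17 significant digits reloads
    # bit-exactly
    return pd.read_csv(path, sep=sep, header=None,
                       float_precision="round_trip").to_numpy(dtype=np.float64)


def load_subject(
    path: str | Path,
    subject_id: str,
    label: int,
    orientation: str = "rois_x_time",
    tr_seconds: float | None = None,
) -> RoiTimeSeries:
    """Load one subject from a delimited-text file.

    ``orientation`` is declared explicitly ('rois_x_time' or
    'time_x_rois'), never guessed from the matrix shape.
    """
    data = _read_matrix(Path(path))
    if orientation == "time_x_rois":
        data = data.T
    elif orientation != "rois_x_time":
        raise ValueError(f"unknown orientation {orientation!r}")
    return RoiTimeSeries(subject_id=subject_id, data=data, label=int(label),
                         tr_seconds=tr_seconds)


def load_cohort(manifest_path: str | Path) -> list[RoiTimeSeries]:
    """Load a cohort from a manifest CSV.

    Required columns: ``subject_id``, ``path``, ``label``.  Optional:
    ``site``, ``orientation``, ``tr_seconds``.  Relative paths are resolved
    against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    for col in ("subject_id", "path", "label"):
        if col not in table.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    cohort = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        cohort.append(
            load_subject(
                p,
                subject_id=str(row.subject_id),
                label=int(row.label),
                orientation=getattr(row, "orientation", "rois_x_time"),
                tr_seconds=getattr(row, "tr_seconds", None),
            )
        )
    return cohort
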