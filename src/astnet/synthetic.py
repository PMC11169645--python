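"""Synthetic ROI time-series cohorts with planted connectivity differences.

The generator emulates the second-order structure the models consume: each
subject is a zero-mean multivariate-normal series whose covariance
switches between a small number of regimes ("states") on a fixed schedule
of contiguous blocks.  ROIs are organized in communities with a common
within-block correlation; the patient group's covariance is perturbed on a
chosen set of edges by a correlation delta, in a chosen subset of states
only — a genuinely *dynamic* group difference that washes out in
full-series statistics.  No hemodynamics, motion or site effects are
simulated; the models only ever see second-order temporal structure, so a
Gaussian regime model is the minimal sufficient emulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .windowing import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["CohortSpec", "generate_cohort", "ground_truth_diff_mask",
           "state_schedule", "write_cohort"]

_EIG_FLOOR = 1e-6  # eigenvalue clip used when repairing an indefinite matrix


def _default_partition(n_rois: int, n_blocks: int = 4) -> dict[int, int]:
    """Contiguous communities of (near-)equal size."""
    size = int(np.ceil(n_rois / n_blocks))
    return {i: min(i // size, n_blocks - 1) for i in range(n_rois)}


def _default_effect_edges(partition: dict[int, int]) -> list[tuple[int, int]]:
    """Ten cross-community edges: a planted 'dysconnected subnetwork'."""
    blocks: dict[int, list[int]] = {}
    for roi, b in sorted(partition.items()):
        blocks.setdefault(b, []).append(roi)
    ids = sorted(blocks)
    edges: list[tuple[int, int]] = []
    pairs = [(ids[i], ids[i + 1]) for i in range(len(ids) - 1)] or [(ids[0], ids[0])]
    k = 0
    while len(edges) < 10:
        ba, bb = pairs[k % len(pairs)]
        i = blocks[ba][(k // len(pairs)) % len(blocks[ba])]
        j = blocks[bb][(k // len(pairs) + 1) % len(blocks[bb])]
        if i != j and (i, j) not in edges and (j, i) not in edges:
            edges.append((min(i, j), max(i, j)))
        k += 1
        if k > 100 * len(pairs):  # tiny graphs: fewer than 10 distinct edges
            break
    return edges


@dataclass
class CohortSpec:
    """Generative conditions for one two-group cohort.

    Defaults describe the desk-scale evaluation cohort used throughout the
    package: 100 subjects per group, 20 ROIs in four communities, 240
    timepoints in two covariance states of 120 timepoints each (six
    windows of 20), and a correlation delta of 0.4 planted on ten
    cross-community edges of the patient group in the second state only.
    """

    n_subjects_per_group: int = 100
    n_rois: int = 20
    n_timepoints: int = 240
    window_length: int = 20
    n_states: int = 2
    community_partition: dict[int, int] | None = None
    within_block_corr: float = 0.3
    between_block_corr: float = 0.0
    effect_edges: list[tuple[int, int]] | None = None
    effect_size: float = 0.4
    affected_states: tuple[int, ...] = (1,)
    noise_sd: float = 1.0
    seed: int = 0
    # per-state scaling of the within-community correlation shared by BOTH
    # groups, so the regimes differ even under the null (effect_size = 0)
    state_corr_scale: tuple[float, ...] | None = None
    align_to_windows: bool = True
    markov_switching: bool = False
    markov_stay_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.community_partition is None:
            self.community_partition = _default_partition(self.n_rois)
        if self.effect_edges is None:
            self.effect_edges = _default_effect_edges(self.community_partition)
        self.effect_edges = [tuple(e) for e in self.effect_edges]
        if self.state_corr_scale is None:
            self.state_corr_scale = tuple(
                1.0 - 0.4 * k / max(1, self.n_states - 1)
                for k in range(self.n_states)
            )
        if len(self.state_corr_scale) != self.n_states:
            raise ValueError("state_corr_scale must have one entry per state")
        if not (0 <= self.within_block_corr < 1 and 0 <= self.between_block_corr < 1):
            raise ValueError("correlations must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(s < 0 or s >= self.n_states for s in self.affected_states):
            raise ValueError("affected_states out of range")
        for i, j in self.effect_edges:
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"invalid effect edge ({i}, {j})")


def _base_correlation(spec: CohortSpec, state: int) -> np.ndarray:
    n = spec.n_rois
    part = spec.community_partition
    same = np.array(
        [[part[i] == part[j] for j in range(n)] for i in range(n)], dtype=bool
    )
    scale = spec.state_corr_scale[state]
    corr = np.where(same, spec.within_block_corr * scale,
                    spec.between_block_corr * scale)
    np.fill_diagonal(corr, 1.0)
    return corr


def _repair_pd(corr: np.ndarray, context: str) -> np.ndarray:
    """Clip eigenvalues and renormalize the diagonal; error if still bad."""
    w = np.linalg.eigvalsh(corr)
    if w.min() > _EIG_FLOOR:
        return corr
    logger.warning("repairing non-PD correlation matrix (%s, min eig %.3g)",
                   context, w.min())
    w, v = np.linalg.eigh(corr)
    fixed = (v * np.maximum(w, _EIG_FLOOR)) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    if np.linalg.eigvalsh(fixed).min() <= 0:
        raise ValueError(f"correlation matrix not repairable ({context})")
    return fixed


def group_state_correlations(spec: CohortSpec) -> np.ndarray:
    """Target correlation matrices, shape ``(2, n_states, N, N)``."""
    out = np.empty((2, spec.n_states, spec.n_rois, spec.n_rois))
    for state in range(spec.n_states):
        base = _base_correlation(spec, state)
        out[0, state] = _repair_pd(base, f"group 0 state {state}")
        pert = base.copy()
        if state in spec.affected_states:
            for i, j in spec.effect_edges:
                pert[i, j] += spec.effect_size
                pert[j, i] = pert[i, j]
            if np.any(np.abs(pert[~np.eye(spec.n_rois, dtype=bool)]) >= 1.0):
                raise ValueError("effect_size pushes a correlation out of (-1, 1)")
        out[1, state] = _repair_pd(pert, f"group 1 state {state}")
    return out


def state_schedule(spec: CohortSpec,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """State index of every timepoint, length ``n_timepoints``.

    Default: contiguous equal blocks (state boundaries fall on window
    boundaries when the block length is a multiple of the window length;
    set ``align_to_windows=False`` to shift the schedule by half a window).
    With ``markov_switching=True`` the state instead evolves as a Markov
    chain over successive windows (requires an rng).
    """
    t_total, k = spec.n_timepoints, spec.n_states
    if spec.markov_switching:
        if rng is None:
            raise ValueError("markov schedule needs an rng")
        stay = spec.markov_stay_prob
        n_win = int(np.ceil(t_total / spec.window_length))
        states = np.empty(n_win, dtype=int)
        states[0] = int(rng.integers(k))
        for w in range(1, n_win):
            if rng.random() < stay:
                states[w] = states[w - 1]
            else:
                others = [s for s in range(k) if s != states[w - 1]]
                states[w] = int(rng.choice(others))
        return np.repeat(states, spec.window_length)[:t_total]
    block = t_total // k
    sched = np.minimum(np.arange(t_total) // max(block, 1), k - 1)
    if not spec.align_to_windows:
        sched = np.roll(sched, spec.window_length // 2)
    return sched


def generate_cohort(spec: CohortSpec) -> list[RoiTimeSeries]:
    """Draw a labeled cohort; deterministic given ``spec.seed``.

    Controls (label 0) come first, then patients (label 1).
    """
    rng = np.random.default_rng(spec.seed)
    corrs = group_state_correlations(spec)
    chols = np.empty_like(corrs)
    for g in range(2):
        for s in range(spec.n_states):
            chols[g, s] = np.linalg.cholesky(corrs[g, s]) * spec.noise_sd
    cohort: list[RoiTimeSeries] = []
    for group in (0, 1):
        for i in range(spec.n_subjects_per_group):
            sched = state_schedule(
                spec, rng if spec.markov_switching else None
            )
            z = rng.standard_normal((spec.n_timepoints, spec.n_rois))
            x = np.empty_like(z)
            for s in range(spec.n_states):
                rows = sched == s
                x[rows] = z[rows] @ chols[group, s].T
            cohort.append(
                RoiTimeSeries(
                    subject_id=f"sub-g{group}-{i:03d}",
                    data=x.T,
                    label=group,
                )
            )
    return cohort


def ground_truth_diff_mask(spec: CohortSpec) -> np.ndarray:
    """Binary ``(n_states, N, N)`` mask: 1 on planted edges in affected states."""
    mask = np.zeros((spec.n_states, spec.n_rois, spec.n_rois), dtype=int)
    for s in spec.affected_states:
        for i, j in spec.effect_edges:
            mask[s, i, j] = 1
            mask[s, j, i] = 1
    return mask


def write_cohort(cohort: list[RoiTimeSeries], out_dir: str | Path,
                 site: str = "synthetic") -> Path:
    """Write one TSV per subject plus a manifest CSV; returns manifest path.

    Matrices are written with 17 significant digits so that a round trip
    through text reproduces every float bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in cohort:
        fname = f"{subject.subject_id}.tsv"
        np.savetxt(out_dir / fname, subject.data, delimiter="\t", fmt="%.17g")
        rows.append(
            {"subject_id": subject.subject_id, "path": fname,
             "label": subject.label, "site": site}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
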