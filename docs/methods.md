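# Methods

This note documents the models implemented in `astnet`, the choices made
where the design was genuinely open, the synthetic cohorts used to
exercise them, and the package's known limitations.

## Problem setting

The package classifies subjects (patient vs. control) from region-of-
interest (ROI) fMRI time series: one real matrix of shape
`n_rois x n_timepoints` per subject, with a binary label.  The working
hypothesis of dynamic functional-connectivity (dFC) analysis is that the
statistical dependencies between ROIs change over the scan, and that the
way they change is discriminative.  The pipeline therefore (1) segments
each series into `T = floor(n_timepoints / L)` non-overlapping windows of
length `L` (trailing remainder discarded and logged; default `L = 20`
timepoints, i.e. 40–50 s at typical TRs, a standard window for stable dFC
estimates), (2) learns a functional-connectivity graph per window, and
(3) summarizes the window sequence with recurrent and attention branches.

## Model

**Adaptive graph learning (AGL).** For a window `G = (x_1..x_N)^T`
(`N x L`), edge weights are

    A_mn = softmax_n( exp( ReLU( w^T |x_m - x_n| ) ) )

with a single learnable weight vector `w` of length `L` shared across
windows and subjects.  `A` is strictly positive and row-stochastic.  Two
consequences worth noting: `w = 0` (or any `w` with all pairwise scores
non-positive) yields the degenerate uniform graph `A = 1/N`; and the
self-score is fixed at `exp(ReLU(0)) = 1`, so a row can never place
dominant weight on its own node.  The regularizer

    L_graph = sum_mn ||x_m - x_n||^2 A_mn + lambda ||A||_F^2

(`lambda = 1e-3` by default; a package choice) rewards giving similar
ROIs stronger edges and penalizes dense graphs.  It is added to the
classification loss (unweighted sum; a coefficient exists and defaults
to 1) rather than minimized alone, which would drive `w` into the
degenerate solution.

**Graph convolution.** Three layers `H^{l+1} = sigma(A H^l W^l)` with
`H^0 = G`, hidden widths `[64, 64, 32]` (a package choice: modest
capacity with a small final width so the second-order matrix is low
rank), each followed by batch normalization (over batch, windows and
nodes per channel), ReLU, and dropout 0.5.  The same `A` is reused by all
layers of one window.  The window's connectivity matrix is
`S_t = H H^T` (symmetric, PSD), and its strict upper triangle
(`N(N-1)/2` values, row-major) is the window's feature vector.

**Feature conditioning.** Raw `S_t` entries grow with the GCN width and
carry a large common offset; each window's flattened vector is therefore
z-scored per subject and window before the temporal branches
(`ModelConfig.feature_norm`, on by default).  Without this the initial
cross-entropy sits around 20 and optimization stalls.  Pearson-based
feature variants are already bounded and are not rescaled.

**Temporal dependency mining (TDM).**
*Local branch:* the window vectors, linearly projected to 64 dimensions
(shared projection), feed a 2-layer bidirectional GRU with 4 units per
direction; the final hidden states of the forward and backward scans are
concatenated (length `2 x units`).  Gates act on `[h_prev, x]`; only the
candidate has a bias.
*Global branch:* each window vector is embedded by a three-layer MLP
(1024/256/32, ReLU, dropout after the first two layers); channel
attention then pools across windows: average- and max-pooling over the 32
channels give two length-`T` descriptors, both pass through one shared
two-layer MLP (`T -> max(1, floor(T/3)) -> T`, ratio 3), their sum is
squashed by a sigmoid into per-window weights in (0, 1), and the weighted
**sum** of window features (a weighted mean differs only by a constant
the next layer absorbs) is the 32-dimensional global output.

**Head and loss.** Branch outputs are concatenated and classified by
three fully connected layers (`-> 32 -> 16 -> 2`, ReLU and dropout
between; widths chosen to taper from the 32-dimensional
branch outputs).  The objective is softmax cross-entropy plus the graph
regularizer summed over a subject's windows and averaged over the batch.
Training uses Adam (lr 1e-3), batch size 16, early stopping on a
training-loss plateau (patience and epoch caps configurable).

**Variants.** A factory builds ablations sharing the exact submodules:
`ASTNet_G` / `ASTNet_L` drop the global / local branch; `GCN_d` replaces
the learned adjacency by row-softmaxed |Pearson| per window (so it
differs from the full model only in how `A` is produced); `AGL_d` drops
the GCN and feeds the symmetrized adjacency's upper triangle to the TDM;
`GCN_s`, `AGL_s`, `MLP_s` are single-full-length-window (static)
counterparts classified through the 1024/256/32 MLP; `MLP_d` (windowed
Pearson + global branch) and `BiGRU` (windowed Pearson + local branch)
are the dynamic baselines.

## Numerical choices

- All arithmetic is float64 on a small in-package reverse-mode autodiff
  engine (`astnet.autodiff`); gradients are finite-difference tested.
- Softmax and log-softmax subtract the row maximum (a constant shift:
  values and gradients are exact).
- `max` reductions route gradient to the first maximum (deterministic
  tie-break).
- `w` is initialized from N(0, 0.1^2) (random normal init; the 0.1 scale
  is a package choice); all parameter initialization, batching and dropout draw
  from generators seeded by `ModelConfig.seed`, so runs are reproducible
  bit for bit.
- Batch normalization uses batch statistics in training and running
  averages (momentum 0.1) in evaluation; evaluation mode is fully
  deterministic.
- Welch's unequal-variance t-test is used for edge-wise group
  differences ("standard t-test" leaves the flavor open); p-values are
  binarized at 0.05 (1 where p > 0.05), without multiple-testing
  correction by default (an optional Benjamini-Hochberg flag exists).
  Degenerate edges (zero variance in both groups, e.g. the diagonal of a
  correlation matrix) report p = 1: no evidence of difference.
- Non-positive-definite synthetic correlation targets are repaired by
  eigenvalue clipping at 1e-6 plus diagonal renormalization, with a
  logged warning; an unrepairable matrix is an error.

## Synthetic cohorts

The generator emulates exactly what the models consume: second-order
temporal structure.  Each subject is a zero-mean multivariate normal
series whose correlation matrix switches between `n_states` regimes on a
fixed schedule of contiguous blocks (aligned to window boundaries by
default; a half-window misalignment flag and a Markov-switching schedule
exist).  ROIs form four equal communities with within-community
correlation 0.3 (scaled per state so the regimes differ for both
groups); the patient group's correlation is raised by `effect_size` on
ten cross-community edges — a planted "dysconnected subnetwork" — in a
chosen subset of states only, making the group difference genuinely
dynamic.  The default cohort used throughout the evaluation is 100
subjects per group, 20 ROIs, 240 timepoints (two states of six windows
each), effect 0.4 in the second state, unit noise.

Deliberately not simulated: hemodynamic response, autocorrelated noise,
motion or site effects, non-Gaussian tails.  Passing tests on these
cohorts therefore demonstrate that the implementation is correct and
that the statistical machinery is calibrated; they do not demonstrate
performance on real BOLD data.

## Evaluation protocol and problem sizes

Experiments in the test suite and the acceptance script use a stratified
70/30 train/test split, the training protocol above capped at 60 epochs
(patience 15), and the cohort defaults described above; these sizes are
the package's desk-scale evaluation conditions.  Group-difference maps
for the planted-edge recovery and null-calibration analyses use the
windowed-Pearson source of `group_difference_maps`, which needs no
trained model and is the ground-truth-recoverable representation on
Gaussian cohorts; the learned-connectivity source (`source="model"`)
computes the same maps from a trained model's per-window `S_t`.

## Known limitations

- On these Gaussian cohorts the windowed Pearson correlation is the
  sufficient statistic for the planted effect, and the baselines that
  consume it directly (e.g. `MLP_d`) separate the groups essentially
  perfectly.  The learned adjacency `A` is equally informative as a
  representation.  The second-order features `S_t = H H^T` taken after
  graph convolution are substantially less informative at this scale:
  because the row-softmax adjacency cannot be self-dominant, each GCN
  layer replaces a node's features by a subject-specific mixture of
  other nodes', which degrades the cross-subject alignment of edge
  features at N = 20.  The full dynamic pipeline consequently trains and
  evaluates correctly but does not reach the held-out accuracy of the
  windowed-correlation baselines on the desk-scale cohorts; the
  acceptance script reports the measured accuracies of both families.
  At atlas scale (N = 116) with strong, anatomically stable community
  structure the mixing is far more consistent across subjects, which is
  the regime the architecture targets.
- The graph regularizer's gradient dwarfs the cross-entropy term for
  `w`; `w` is effectively shaped by the smoothness objective while the
  remaining parameters are shaped by classification.
- Per-site series lengths imply different window counts `T`; models are
  built per cohort (the attention MLP is `T`-specific) rather than
  padding across sites.
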