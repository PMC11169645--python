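"""Independent scalar/loop oracles used to cross-check the implementation.

Everything here is written with explicit Python loops over scalars (or
calls into a different library routine than the implementation uses), so
that agreement with the package is a genuine two-route check.
"""

import math

import numpy as np


def adjacency_oracle(segment, omega):
    """Entry-by-entry softmax(ReLU(w^T |x_m - x_n|)) with scalar loops."""
    seg = np.asarray(segment, dtype=float)
    n, length = seg.shape
    scores = np.zeros((n, n))
    for m in range(n):
        for nn in range(n):
            s = 0.0
            for f in range(length):
                s += omega[f] * abs(seg[m, f] - seg[nn, f])
            scores[m, nn] = max(s, 0.0)
    out = np.zeros((n, n))
    for m in range(n):
        row = [math.exp(scores[m, nn]) for nn in range(n)]
        z = sum(row)
        for nn in range(n):
            out[m, nn] = row[nn] / z
    return out


def graph_loss_oracle(segment, adjacency, lam):
    """Double-loop smoothness + Frobenius penalty."""
    seg = np.asarray(segment, dtype=float)
    a = np.asarray(adjacency, dtype=float)
    n = seg.shape[0]
    total = 0.0
    for m in range(n):
        for nn in range(n):
            d2 = sum((seg[m, f] - seg[nn, f]) ** 2 for f in range(seg.shape[1]))
            total += d2 * a[m, nn]
    frob = sum(a[m, nn] ** 2 for m in range(n) for nn in range(n))
    return total + lam * frob


def matmul_oracle(a, b):
    """Triple-loop matrix product."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    out = np.zeros((a.shape[0], b.shape[1]))
    for i in range(a.shape[0]):
        for j in range(b.shape[1]):
            out[i, j] = sum(a[i, k] * b[k, j] for k in range(a.shape[1]))
    return out


def gcn_layer_oracle(adjacency, features, weights, relu=True):
    """sigma(A H W) with loop-based products."""
    h = matmul_oracle(matmul_oracle(adjacency, features), weights)
    if relu:
        h = np.maximum(h, 0.0)
    return h


def connectivity_oracle(features):
    """Double-loop dot products S_mn = h_m . h_n."""
    h = np.asarray(features, float)
    n = h.shape[0]
    out = np.zeros((n, n))
    for m in range(n):
        for nn in range(n):
            out[m, nn] = sum(h[m, k] * h[nn, k] for k in range(h.shape[1]))
    return out


def _sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def gru_step_oracle(x, h_prev, W_z, W_r, W_h, b_h):
    """Scalar step-by-step GRU update on [h_prev, x]."""
    x = np.asarray(x, float)
    h_prev = np.asarray(h_prev, float)
    hx = np.concatenate([h_prev, x])
    hidden = h_prev.shape[0]
    z = np.array([_sigmoid(sum(hx[k] * W_z[k, j] for k in range(hx.size)))
                  for j in range(hidden)])
    r = np.array([_sigmoid(sum(hx[k] * W_r[k, j] for k in range(hx.size)))
                  for j in range(hidden)])
    rhx = np.concatenate([r * h_prev, x])
    h_tilde = np.array(
        [math.tanh(sum(rhx[k] * W_h[k, j] for k in range(rhx.size)) + b_h[j])
         for j in range(hidden)]
    )
    return (1.0 - z) * h_prev + z * h_tilde


def mlp_oracle(vector, weights, biases):
    """Loop-based affine + ReLU stack (ReLU after every layer)."""
    h = np.asarray(vector, float)
    for w, b in zip(weights, biases):
        out = np.zeros(w.shape[1])
        for j in range(w.shape[1]):
            out[j] = sum(h[k] * w[k, j] for k in range(w.shape[0])) + b[j]
        h = np.maximum(out, 0.0)
    return h


def attention_oracle(features, w1, b1, w2, b2):
    """Scalar channel attention: pooled descriptors -> shared MLP -> sigmoid."""
    f = np.asarray(features, float)  # (T, C)
    t = f.shape[0]
    avg = np.array([f[i].mean() for i in range(t)])
    mx = np.array([f[i].max() for i in range(t)])

    def shared(v):
        hidden = np.maximum(
            np.array([sum(v[k] * w1[k, j] for k in range(t)) + b1[j]
                      for j in range(w1.shape[1])]), 0.0)
        return np.array([sum(hidden[k] * w2[k, j] for k in range(w2.shape[0]))
                         + b2[j] for j in range(t)])

    logits = shared(avg) + shared(mx)
    weights = np.array([_sigmoid(v) for v in logits])
    pooled = np.zeros(f.shape[1])
    for i in range(t):
        pooled += weights[i] * f[i]
    return pooled, weights


def welch_ttest_oracle(a, b):
    """Two-sample unequal-variance t-test p-value from the scalar formulas."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    tstat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * tdist.sf(abs(tstat), df)


def cross_entropy_oracle(logits, label):
    """Scalar softmax cross-entropy."""
    logits = np.asarray(logits, float)
    exps = [math.exp(v) for v in logits]
    p = exps[label] / sum(exps)
    return -math.log(p)
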