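"""Independent straight-line / loop-based reference implementations.

These oracles deliberately avoid the package's vectorized code paths: plain
Python loops over batch, channel and spatial indices, direct convolution
sums, and per-pixel tallies.  They are slow and only meant for tiny inputs.
"""

from __future__ import annotations

import numpy as np


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=np.float64)))


def channel_attention_loops(x, p):
    """Per-position MLP channel gate, one pixel at a time."""
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros_like(x)
    n_, c_, h_, w_ = x.shape
    for n in range(n_):
        for h in range(h_):
            for w in range(w_):
                v = x[n, :, h, w]
                z = np.maximum(p.w1.astype(np.float64) @ v + p.b1, 0.0)
                gate = sigmoid(p.w2.astype(np.float64) @ z + p.b2)
                out[n, :, h, w] = gate * v
    return out


def channel_shuffle_loops(x, groups=4):
    """Index-by-index reshape(groups, C/g) -> transpose -> flatten permutation."""
    x = np.asarray(x)
    n_, c_, h_, w_ = x.shape
    cg = c_ // groups
    out = np.zeros_like(x)
    for i in range(groups):
        for k in range(cg):
            out[:, k * groups + i] = x[:, i * cg + k]
    return out


def conv2d_loops(x, w, b, padding):
    """Direct convolution sum, stride 1."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    n_, cin, h_, w_ = x.shape
    cout, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out = np.zeros((n_, cout, h_, w_))
    for n in range(n_):
        for o in range(cout):
            for y in range(h_):
                for xx in range(w_):
                    acc = 0.0
                    for c in range(cin):
                        for i in range(kh):
                            for j in range(kw):
                                acc += xp[n, c, y + i, xx + j] * w[o, c, i, j]
                    out[n, o, y, xx] = acc + (b[o] if b is not None else 0.0)
    return out


def batchnorm_loops(x, bn, mode):
    x = np.asarray(x, dtype=np.float64)
    if mode == "train":
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
    else:
        mu, var = bn.running_mean, bn.running_var
    out = np.zeros_like(x)
    for c in range(x.shape[1]):
        out[:, c] = ((x[:, c] - mu[c]) / np.sqrt(var[c] + bn.eps)
                     * bn.gamma[c] + bn.beta[c])
    return out


def spatial_attention_loops(x, p, mode="eval"):
    """conv7x7 -> BN -> ReLU -> conv7x7 -> BN -> sigmoid gate, all by loops."""
    h = conv2d_loops(x, p.conv1_w, p.conv1_b, padding=3)
    h = np.maximum(batchnorm_loops(h, p.bn1, mode), 0.0)
    h = conv2d_loops(h, p.conv2_w, p.conv2_b, padding=3)
    return sigmoid(batchnorm_loops(h, p.bn2, mode)) * np.asarray(x, dtype=np.float64)


def confusion_loops(pred, truth):
    """Per-pixel double-loop confusion tally."""
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j] == 255, truth[i, j] == 255
            if p and t:
                tp += 1
            elif p:
                fp += 1
            elif t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn
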