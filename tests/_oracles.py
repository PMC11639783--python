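"""Straight-line loop reference implementations of the attention math.

These deliberately avoid the package's tensor engine: plain Python loops
and elementary numpy scalar arithmetic only, so they serve as independent
oracles for the vectorized block implementations.
"""

import math

import numpy as np


def sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


def gap_oracle(x):
    h, w, c = x.shape
    out = np.zeros(c)
    for k in range(c):
        s = 0.0
        for i in range(h):
            for j in range(w):
                s += x[i, j, k]
        out[k] = s / (h * w)
    return out


def gmp_oracle(x):
    h, w, c = x.shape
    out = np.full(c, -np.inf)
    for k in range(c):
        for i in range(h):
            for j in range(w):
                out[k] = max(out[k], x[i, j, k])
    return out


def conv2d_same_oracle(x, w, b):
    """Stride-1 SAME convolution by explicit loops (odd kernels)."""
    h, wd, c = x.shape
    kh, kw, _, f = w.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    out = np.zeros((h, wd, f))
    for i in range(h):
        for j in range(wd):
            for m in range(f):
                s = b[m]
                for di in range(kh):
                    for dj in range(kw):
                        ii, jj = i + di - ph, j + dj - pw
                        if 0 <= ii < h and 0 <= jj < wd:
                            for k in range(c):
                                s += x[ii, jj, k] * w[di, dj, k, m]
                out[i, j, m] = s
    return out


def bn_infer_oracle(x, gamma, beta, mean, var, eps):
    h, w, c = x.shape
    out = np.zeros_like(x)
    for k in range(c):
        scale = gamma[k] / math.sqrt(var[k] + eps)
        for i in range(h):
            for j in range(w):
                out[i, j, k] = (x[i, j, k] - mean[k]) * scale + beta[k]
    return out


def channel_gate_oracle(x, dense_w, dense_b):
    """Sigmoid channel weights from [GAP, GMP] through one affine layer."""
    c = x.shape[2]
    v = np.concatenate([gap_oracle(x), gmp_oracle(x)])
    out = np.zeros(c)
    for m in range(c):
        z = dense_b[m]
        for k in range(2 * c):
            z += v[k] * dense_w[k, m]
        out[m] = sigmoid(z)
    return out


def channel_attention_oracle(x, dense_w, dense_b):
    w = channel_gate_oracle(x, dense_w, dense_b)
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            for k in range(x.shape[2]):
                out[i, j, k] = x[i, j, k] * w[k]
    return out


def spatial_gate_oracle(x, conv_w, conv_b):
    h, w, c = x.shape
    pooled = np.zeros((h, w, 2))
    for i in range(h):
        for j in range(w):
            s, mx = 0.0, -np.inf
            for k in range(c):
                s += x[i, j, k]
                mx = max(mx, x[i, j, k])
            pooled[i, j, 0] = s / c
            pooled[i, j, 1] = mx
    z = conv2d_same_oracle(pooled, conv_w, conv_b)
    gate = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            gate[i, j] = sigmoid(z[i, j, 0])
    return gate


def spatial_attention_oracle(x, conv_w, conv_b):
    gate = spatial_gate_oracle(x, conv_w, conv_b)
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            for k in range(x.shape[2]):
                out[i, j, k] = x[i, j, k] * gate[i, j]
    return out


def softplus_oracle(x):
    out = np.zeros_like(x)
    for idx in np.ndindex(x.shape):
        out[idx] = math.log1p(math.exp(-abs(x[idx]))) + max(x[idx], 0.0)
    return out


def _preamble_oracle(x, p):
    """conv -> batch-norm (inference, running stats) -> softplus."""
    conv = conv2d_same_oracle(x, p.conv.w.data, p.conv.b.data)
    bn = bn_infer_oracle(conv, p.bn.gamma.data, p.bn.beta.data,
                         p.bn.running_mean, p.bn.running_var, p.bn.eps)
    return softplus_oracle(bn)


def srab_oracle(x, p):
    act = _preamble_oracle(x, p)
    ca = channel_attention_oracle(act, p.channel_dense.w.data, p.channel_dense.b.data)
    sa = spatial_attention_oracle(ca, p.spatial_conv.w.data, p.spatial_conv.b.data)
    if p.res_proj is not None:
        res = conv2d_same_oracle(x, p.res_proj.w.data, p.res_proj.b.data)
    else:
        res = x
    return sa + res


def attention_block_oracle(x, p):
    ca = channel_attention_oracle(x, p.channel_dense.w.data, p.channel_dense.b.data)
    return spatial_attention_oracle(ca, p.spatial_conv.w.data, p.spatial_conv.b.data)


def reverse_attention_oracle(x, p):
    act = _preamble_oracle(x, p)
    gate = channel_gate_oracle(act, p.channel_dense.w.data, p.channel_dense.b.data)
    if p.complement_gate:
        gate = 1.0 - gate
    out = np.zeros_like(act)
    for i in range(act.shape[0]):
        for j in range(act.shape[1]):
            for k in range(act.shape[2]):
                out[i, j, k] = act[i, j, k] * gate[k]
    return out


def randomize_block(p, rng):
    """Fill every learnable parameter and running statistic with random values."""
    for param in p.parameters():
        param.data = rng.normal(0.0, 0.6, param.data.shape)
    if p.bn is not None:
        p.bn.running_mean = rng.normal(0.0, 0.5, p.bn.running_mean.shape)
        p.bn.running_var = rng.uniform(0.3, 2.0, p.bn.running_var.shape)
    return p
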