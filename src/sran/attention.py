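"""Channel/spatial attention feature-map operators.

Three blocks refine convolutional feature maps for identity embedding:

* **Self-residual attention block (SRAB)** — conv -> batch-norm -> Softplus,
  then a channel gate computed from concatenated global average/max pooled
  channel statistics, a spatial gate computed from channel-reduced
  average/max maps, and an additive residual from the block input (1x1
  projected when the channel counts differ).
* **Attention block** — the same channel gate followed by the spatial gate,
  applied directly to the input; no convolution preamble and no residual.
* **Reverse attention block** — conv -> batch-norm -> Softplus followed by a
  channel gate; intended to re-emphasize regions downweighted earlier.  The
  literal form is a second channel attention; the ``complement_gate`` flag
  swaps the gate for its complement (1 - weights).

All gates use the logistic sigmoid, so gate weights lie strictly in (0, 1).
Functional wrappers accept a single H x W x C map or an N x H x W x C batch
of plain numpy arrays; block state lives in :class:`BlockParams`.
"""

from __future__ import annotations

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .layers import BatchNorm2d, Conv2D, Dense, Layer


class BlockParams(Layer):
    """Learnable state for one attention block.

    Built with one of the :meth:`for_srab`, :meth:`for_attention`,
    :meth:`for_reverse` constructors.  ``training_mode`` selects batch-norm
    behavior; embedding extraction always runs with it off.
    """

    def __init__(self, kind, c_in, conv_filters=None, conv_kernel=3,
                 spatial_kernel=7, complement_gate=False, rng=None):
        rng = rng or np.random.default_rng(0)
        if kind not in ("srab", "attention", "reverse"):
            raise ValueError(f"unknown block kind {kind!r}")
        self.kind = kind
        self.c_in = int(c_in)
        self.conv_kernel = conv_kernel
        self.complement_gate = bool(complement_gate)
        self.training_mode = False
        if kind in ("srab", "reverse"):
            if conv_filters is None or conv_filters < 1:
                raise ValueError("conv_filters must be a positive int")
            self.conv_filters = int(conv_filters)
            self.conv = Conv2D(c_in, conv_filters, kernel=conv_kernel, rng=rng)
            self.bn = BatchNorm2d(conv_filters)
            gate_c = conv_filters
        else:
            self.conv_filters = int(c_in)
            self.conv = None
            self.bn = None
            gate_c = c_in
        # channel gate: affine map from the concatenated [GAP, GMP] 2C vector
        self.channel_dense = Dense(2 * gate_c, gate_c, rng=rng)
        if kind in ("srab", "attention"):
            self.spatial_conv = Conv2D(2, 1, kernel=spatial_kernel, rng=rng)
        else:
            self.spatial_conv = None
        if kind == "srab":
            self.res_proj = (
                Conv2D(c_in, conv_filters, kernel=1, rng=rng)
                if c_in != conv_filters
                else None
            )
        else:
            self.res_proj = None

    # constructors -------------------------------------------------------
    @classmethod
    def for_srab(cls, c_in, conv_filters, conv_kernel=3, spatial_kernel=7, rng=None):
        return cls("srab", c_in, conv_filters, conv_kernel, spatial_kernel, rng=rng)

    @classmethod
    def for_attention(cls, channels, spatial_kernel=7, rng=None):
        return cls("attention", channels, spatial_kernel=spatial_kernel, rng=rng)

    @classmethod
    def for_reverse(cls, c_in, conv_filters, conv_kernel=3, complement_gate=False, rng=None):
        return cls("reverse", c_in, conv_filters, conv_kernel,
                   complement_gate=complement_gate, rng=rng)

    def zero_(self):
        """Set every learnable parameter to zero (analytic test helper)."""
        for p in self.parameters():
            p.data = np.zeros_like(p.data)
        if self.bn is not None:
            # batch-norm scale stays 1 so inference with running stats
            # (mean 0, variance 1) is an epsilon-scaled identity
            self.bn.gamma.data = np.ones_like(self.bn.gamma.data)
            self.bn.running_mean[:] = 0.0
            self.bn.running_var[:] = 1.0
        return self


# -- tensor-graph forms (shared by functional API and the network) -------
def channel_gate_t(x: Tensor, dense: Dense) -> Tensor:
    """Sigmoid channel weights from concatenated [GAP, GMP], shape (N,1,1,C)."""
    gap = T.reduce_mean(x, axis=(1, 2))        # (N, C)
    gmp = T.reduce_max(x, axis=(1, 2))         # (N, C)
    z = dense(T.concat([gap, gmp], axis=1))    # (N, C)
    w = T.sigmoid(z)
    n, c = w.data.shape
    return T.reshape(w, (n, 1, 1, c))


def spatial_gate_t(x: Tensor, conv: Conv2D) -> Tensor:
    """Sigmoid location weights from [channel-avg, channel-max], (N,H,W,1)."""
    avg = T.reduce_mean(x, axis=3, keepdims=True)
    mx = T.reduce_max(x, axis=3, keepdims=True)
    return T.sigmoid(conv(T.concat([avg, mx], axis=3)))


def srab_forward_t(x: Tensor, p: BlockParams, training=False, check_finite=False) -> Tensor:
    conv_act = T.softplus(p.bn(p.conv(x), training=training))
    if check_finite:
        _finite(conv_act, "conv/batch-norm/softplus preamble")
    attended = T.mul(conv_act, channel_gate_t(conv_act, p.channel_dense))
    attended = T.mul(attended, spatial_gate_t(attended, p.spatial_conv))
    if check_finite:
        _finite(attended, "attention gating")
    res = p.res_proj(x) if p.res_proj is not None else x
    out = T.add(attended, res)
    if check_finite:
        _finite(out, "residual sum")
    return out


def attention_block_forward_t(x: Tensor, p: BlockParams) -> Tensor:
    attended = T.mul(x, channel_gate_t(x, p.channel_dense))
    return T.mul(attended, spatial_gate_t(attended, p.spatial_conv))


def reverse_attention_forward_t(x: Tensor, p: BlockParams, training=False) -> Tensor:
    conv_act = T.softplus(p.bn(p.conv(x), training=training))
    gate = channel_gate_t(conv_act, p.channel_dense)
    if p.complement_gate:
        gate = T.add(T.mul(gate, -1.0), 1.0)
    return T.mul(conv_act, gate)


def _finite(t: Tensor, stage: str):
    if not np.all(np.isfinite(t.data)):
        raise FloatingPointError(f"non-finite values after {stage}")


# -- functional numpy API ------------------------------------------------
def _as_batch(x):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected H x W x C or N x H x W x C, got shape {x.shape}")


def _check_map(x):
    if x.shape[1] < 1 or x.shape[2] < 1 or x.shape[3] < 1:
        raise ValueError("feature map must have H, W, C >= 1")
    if x.size == 0:
        raise ValueError("empty feature map")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")


def _check_channels(x, expected, what):
    if x.shape[3] != expected:
        raise ValueError(
            f"{what}: input has {x.shape[3]} channels but parameters were "
            f"built for {expected}"
        )


def global_average_pool(x) -> np.ndarray:
    """Per-channel mean over all spatial locations (length-C vector)."""
    xb, single = _as_batch(x)
    _check_map(xb)
    out = xb.mean(axis=(1, 2))
    return out[0] if single else out


def global_max_pool(x) -> np.ndarray:
    """Per-channel max over all spatial locations (length-C vector)."""
    xb, single = _as_batch(x)
    _check_map(xb)
    out = xb.max(axis=(1, 2))
    return out[0] if single else out


def channel_attention_weights(x, p: BlockParams) -> np.ndarray:
    """The (0,1) channel gate itself (length-C, or N x C for a batch)."""
    xb, single = _as_batch(x)
    _check_map(xb)
    _check_channels(xb, p.channel_dense.units, "channel attention")
    w = channel_gate_t(Tensor(xb), p.channel_dense).data.reshape(xb.shape[0], -1)
    return w[0] if single else w


def channel_attention_apply(x, p: BlockParams) -> np.ndarray:
    """Reweight channels by the sigmoid gate; shape is preserved."""
    xb, single = _as_batch(x)
    _check_map(xb)
    _check_channels(xb, p.channel_dense.units, "channel attention")
    out = T.mul(Tensor(xb), channel_gate_t(Tensor(xb), p.channel_dense)).data
    return out[0] if single else out


def spatial_attention_weights(x, p: BlockParams) -> np.ndarray:
    xb, single = _as_batch(x)
    _check_map(xb)
    if p.spatial_conv is None:
        raise ValueError("block has no spatial gate")
    w = spatial_gate_t(Tensor(xb), p.spatial_conv).data
    return w[0] if single else w


def spatial_attention_apply(x, p: BlockParams) -> np.ndarray:
    """Reweight locations by the sigmoid gate broadcast across channels."""
    xb, single = _as_batch(x)
    _check_map(xb)
    if p.spatial_conv is None:
        raise ValueError("block has no spatial gate")
    out = T.mul(Tensor(xb), spatial_gate_t(Tensor(xb), p.spatial_conv)).data
    return out[0] if single else out


def srab_forward(x, p: BlockParams) -> np.ndarray:
    """Self-residual attention block on a plain array (inference by default)."""
    xb, single = _as_batch(x)
    _check_map(xb)
    _check_channels(xb, p.conv.c_in, "SRAB")
    out = srab_forward_t(Tensor(xb), p, training=p.training_mode, check_finite=True).data
    return out[0] if single else out


def attention_block_forward(x, p: BlockParams) -> np.ndarray:
    xb, single = _as_batch(x)
    _check_map(xb)
    _check_channels(xb, p.channel_dense.units, "attention block")
    out = attention_block_forward_t(Tensor(xb), p).data
    return out[0] if single else out


def reverse_attention_forward(x, p: BlockParams) -> np.ndarray:
    xb, single = _as_batch(x)
    _check_map(xb)
    _check_channels(xb, p.conv.c_in, "reverse attention block")
    out = reverse_attention_forward_t(Tensor(xb), p, training=p.training_mode).data
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values in reverse attention output")
    return out[0] if single else out
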