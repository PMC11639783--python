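"""Trainable layers (convolution, dense, batch normalization) and Adam.

Parameters are :class:`~sran._tensor.Tensor` objects with
``requires_grad=True``.  Weight initialization is He-normal drawn from a
seeded :class:`numpy.random.Generator`, so a model built from the same
configuration and seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import _tensor as T
from ._tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Layer:
    """Base class: tracks parameters and non-trainable state arrays."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.parameters())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters plus running statistics."""
        out = {}
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                out[name] = v.data
            elif isinstance(v, np.ndarray):
                out[name] = v
            elif isinstance(v, Layer):
                for k, arr in v.state_arrays().items():
                    out[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Layer):
                        for k, arr in item.state_arrays().items():
                            out[f"{name}.{i}.{k}"] = arr
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix=""):
        for name, v in list(vars(self).items()):
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = np.array(state[key], dtype=np.float64)
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.array(state[key], dtype=np.float64))
            elif isinstance(v, Layer):
                v.load_state_arrays(state, prefix=f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Layer):
                        item.load_state_arrays(state, prefix=f"{key}.{i}.")


class Conv2D(Layer):
    def __init__(self, c_in, filters, kernel=3, stride=1, padding="same", rng=None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        fan_in = kernel * kernel * c_in
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, c_in, filters)))
        self.b = Parameter(np.zeros(filters))
        self.c_in = c_in
        self.filters = filters

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class Dense(Layer):
    def __init__(self, c_in, units, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, units)))
        self.b = Parameter(np.zeros(units))
        self.c_in = c_in
        self.units = units

    def __call__(self, x: Tensor) -> Tensor:
        return T.add(T.matmul(x, self.w), self.b)


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel, NHWC layout.

    Training mode normalizes with batch statistics and updates exponential
    running statistics; inference mode uses the stored running statistics.
    """

    def __init__(self, channels, eps=1e-3, momentum=0.99):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, training=False) -> Tensor:
        if training:
            mu = T.reduce_mean(x, axis=(0, 1, 2))
            centered = T.add(x, T.mul(mu, -1.0))
            var = T.reduce_mean(T.mul(centered, centered), axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data
            self.running_var = m * self.running_var + (1 - m) * var.data
            inv = T.power(T.add(var, self.eps), -0.5)
            return T.add(T.mul(T.mul(centered, inv), self.gamma), self.beta)
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)  # constants
        shift = self.beta.data - self.running_mean * scale
        return T.add(T.mul(x, Tensor(scale)), Tensor(shift))


class Adam:
    """Adam optimizer with bias correction; state keyed by parameter order."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
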