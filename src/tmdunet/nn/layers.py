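"""Layer objects: trainable parameters plus the op that applies them."""
from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor
from . import ops

__all__ = ["Conv2d", "ConvTranspose2d", "BatchNorm2d", "Layer", "he_normal"]


def he_normal(shape, fan_in, rng):
    """Truncated (2 sigma) normal with variance 2/fan_in, after He et al."""
    std = np.sqrt(2.0 / fan_in)
    x = rng.standard_normal(shape)
    while True:
        bad = np.abs(x) > 2.0
        if not bad.any():
            break
        x[bad] = rng.standard_normal(bad.sum())
    return (x * std).astype(np.float32)


class Layer:
    def parameters(self):
        return [v for v in vars(self).values() if isinstance(v, Parameter)]

    @property
    def n_params(self):
        return sum(p.size for p in self.parameters())


class Conv2d(Layer):
    """Stride-1, size-preserving convolution, optionally dilated."""

    def __init__(self, cin, cout, kernel=3, dilation=1, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel * kernel
        self.weight = Parameter(he_normal((cout, cin, kernel, kernel), fan_in, rng))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))
        self.cin, self.cout, self.kernel, self.dilation = cin, cout, kernel, dilation

    def __call__(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.weight, self.bias, self.dilation)


class ConvTranspose2d(Layer):
    """Learned upsampling: kernel = stride (default 2), spatial size x kernel."""

    def __init__(self, cin, cout, kernel=2, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel * kernel
        self.weight = Parameter(he_normal((cin, cout, kernel, kernel), fan_in, rng))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))
        self.cin, self.cout, self.kernel = cin, cout, kernel

    def __call__(self, x: Tensor) -> Tensor:
        return ops.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-3):
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps, self.c = momentum, eps, c

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ops.batch_norm(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training, self.momentum, self.eps)
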