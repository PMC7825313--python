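"""Differentiable array operations used by the network layers."""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

__all__ = [
    "conv2d", "conv_transpose2d", "max_pool2", "concat",
    "relu", "sigmoid", "batch_norm", "dropout",
]


def _im2col(x, k, dilation):
    """(N,C,H,W) -> column matrix (N*H*W, C*k*k) for a same-padded,
    stride-1 convolution with the given dilation."""
    n, c, h, w = x.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ek = dilation * (k - 1) + 1
    win = sliding_window_view(xp, (ek, ek), axis=(2, 3))  # N,C,H,W,ek,ek
    taps = win[..., ::dilation, ::dilation]               # N,C,H,W,k,k
    cols = taps.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _conv_forward(x, w, b, dilation):
    n, c, h, ww = x.shape
    cout = w.shape[0]
    k = w.shape[2]
    cols = _im2col(x, k, dilation)
    wmat = w.reshape(cout, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b
    return out.reshape(n, h, ww, cout).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, weight, bias, dilation: int = 1) -> Tensor:
    """Stride-1, size-preserving (odd-kernel) 2-D convolution.

    weight: (cout, cin, k, k); bias: (cout,) Parameter or None.
    """
    k = weight.data.shape[2]
    y, cols = _conv_forward(x.data, weight.data,
                            None if bias is None else bias.data, dilation)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents)

    def backward(g):
        n, cout, h, w_ = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        weight.accumulate((gmat.T @ cols).reshape(weight.data.shape))
        if bias is not None:
            bias.accumulate(gmat.sum(axis=0))
        # grad wrt input: same-padded dilated conv of g with the rotated,
        # channel-transposed kernel (valid because stride is 1 and padding
        # is symmetric for odd k)
        wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = _conv_forward(g, wflip, None, dilation)
        x.accumulate(dx)

    out._backward = backward
    return out


def conv_transpose2d(x: Tensor, weight, bias) -> Tensor:
    """Transposed convolution with kernel = stride (non-overlapping blocks),
    doubling (for k=2) each spatial dimension.

    weight: (cin, cout, k, k).
    """
    n, c, h, w_ = x.data.shape
    cin, cout, k, _ = weight.data.shape
    t = np.einsum("nchw,cdij->ndhiwj", x.data, weight.data, optimize=True)
    y = t.reshape(n, cout, h * k, w_ * k)
    if bias is not None:
        y = y + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents)

    def backward(g):
        gb = g.reshape(n, cout, h, k, w_, k)
        x.accumulate(np.einsum("ndhiwj,cdij->nchw", gb, weight.data,
                               optimize=True))
        weight.accumulate(np.einsum("nchw,ndhiwj->cdij", x.data, gb,
                                    optimize=True))
        if bias is not None:
            bias.accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = backward
    return out


def max_pool2(x: Tensor) -> Tensor:
    """2x2, stride-2 max pooling; ties route the gradient to the first
    maximal element of each window."""
    n, c, h, w = x.data.shape
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, (x,))

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2) \
                  .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x.accumulate(dx)

    out._backward = backward
    return out


def concat(tensors) -> Tensor:
    """Channel-axis concatenation."""
    tensors = list(tensors)
    if len(tensors) == 1:
        return tensors[0]
    sizes = [t.data.shape[1] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), tensors)

    def backward(g):
        off = 0
        for t, s in zip(tensors, sizes):
            t.accumulate(g[:, off:off + s])
            off += s

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, (x,))
    out._backward = lambda g: x.accumulate(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    pos = x.data >= 0
    e = np.exp(np.where(pos, -x.data, x.data))   # always exp of a negative
    y = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e)).astype(np.float32)
    out = Tensor(y, (x,))
    out._backward = lambda g: x.accumulate(g * y * (1.0 - y))
    return out


def batch_norm(x: Tensor, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.9,
               eps: float = 1e-3) -> Tensor:
    """Per-channel batch normalization over the (N,H,W) axes.

    running_mean / running_var are plain float32 arrays updated in place
    during training and used verbatim at inference.
    """
    if training:
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1 - momentum) * mu
        running_var *= momentum
        running_var += (1 - momentum) * var
        inv = 1.0 / np.sqrt(var + eps)
        xc = x.data - mu[None, :, None, None]
        xhat = xc * inv[None, :, None, None]
        y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        out = Tensor(y, (x, gamma, beta))

        def backward(g):
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta.accumulate(g.sum(axis=(0, 2, 3)))
            dxhat = g * gamma.data[None, :, None, None]
            s1 = dxhat.sum(axis=(0, 2, 3))
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3))
            dx = (dxhat - (s1[None, :, None, None]
                           + xhat * s2[None, :, None, None]) / m) \
                * inv[None, :, None, None]
            x.accumulate(dx)

        out._backward = backward
        return out

    inv = 1.0 / np.sqrt(running_var + eps)
    scale = gamma.data * inv
    y = x.data * scale[None, :, None, None] \
        + (beta.data - running_mean * scale)[None, :, None, None]
    out = Tensor(y, (x, gamma, beta))

    def backward_eval(g):
        xhat = (x.data - running_mean[None, :, None, None]) \
            * inv[None, :, None, None]
        gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta.accumulate(g.sum(axis=(0, 2, 3)))
        x.accumulate(g * scale[None, :, None, None])

    out._backward = backward_eval
    return out


def dropout(x: Tensor, rate: float, training: bool, rng) -> Tensor:
    """Inverted dropout; identity at inference or rate 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    out = Tensor(x.data * mask, (x,))
    out._backward = lambda g: x.accumulate(g * mask)
    return out
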