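"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the shimming regressor needs: strided 1D convolution (im2col),
ReLU, inverted dropout, max-pooling, layer normalization, dense layers, an
LSTM cell, Huber loss and Adam.  Every ``*_forward`` returns ``(out,
cache)`` and the matching ``*_backward`` consumes the upstream gradient
and the cache.  All arrays are float64; gradients are verified against
numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv1d_forward",
    "conv1d_backward",
    "relu_forward",
    "relu_backward",
    "dropout_forward",
    "dropout_backward",
    "maxpool1d_forward",
    "maxpool1d_backward",
    "layernorm_forward",
    "layernorm_backward",
    "dense_forward",
    "dense_backward",
    "lstm_step_forward",
    "lstm_step_backward",
    "huber_loss",
    "Adam",
    "conv_output_length",
]


def conv_output_length(L: int, kernel: int, stride: int) -> int:
    if L < kernel:
        raise ValueError(f"input length {L} shorter than kernel {kernel}")
    return (L - kernel) // stride + 1


def conv1d_forward(x, W, b, stride):
    """x: (B, C, L), W: (F, C, K), b: (F,) -> out (B, F, Lo)."""
    K = W.shape[2]
    view = sliding_window_view(x, K, axis=2)[:, :, ::stride]  # (B, C, Lo, K)
    out = np.tensordot(view, W, axes=([1, 3], [1, 2]))        # (B, Lo, F)
    out = np.ascontiguousarray(out.transpose(0, 2, 1)) + b[None, :, None]
    return out, (x.shape, view, W, stride)


def conv1d_backward(dout, cache):
    x_shape, view, W, stride = cache
    K = W.shape[2]
    Lo = dout.shape[2]
    dW = np.tensordot(dout, view, axes=([0, 2], [0, 2]))      # (F, C, K)
    db = dout.sum(axis=(0, 2))
    dcols = np.tensordot(dout.transpose(0, 2, 1), W, axes=(2, 0))  # (B, Lo, C, K)
    dx = np.zeros(x_shape)
    idx = stride * np.arange(Lo)
    for k in range(K):
        dx[:, :, idx + k] += dcols[:, :, :, k].transpose(0, 2, 1)
    return dx, dW, db


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout, mask):
    return dout * mask


def dropout_forward(x, rate, rng, train):
    if not train or rate <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


def dropout_backward(dout, mask):
    return dout if mask is None else dout * mask


def maxpool1d_forward(x, size):
    """x: (B, C, L) -> (B, C, L // size); trailing remainder is dropped."""
    if size <= 1:
        return x, None
    B, C, L = x.shape
    Lo = L // size
    xr = x[:, :, : Lo * size].reshape(B, C, Lo, size)
    arg = xr.argmax(axis=3)
    out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return out, (x.shape, arg, size)


def maxpool1d_backward(dout, cache):
    if cache is None:
        return dout
    x_shape, arg, size = cache
    B, C, L = x_shape
    Lo = L // size
    dxr = np.zeros((B, C, Lo, size))
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=3)
    dx = np.zeros(x_shape)
    dx[:, :, : Lo * size] = dxr.reshape(B, C, Lo * size)
    return dx


def layernorm_forward(x, gamma, beta, eps=1e-5):
    """Normalize over the last axis; x: (..., D)."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * gamma + beta, (xhat, inv, gamma)


def layernorm_backward(dout, cache):
    xhat, inv, gamma = cache
    D = xhat.shape[-1]
    dgamma = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    dbeta = dout.sum(axis=tuple(range(dout.ndim - 1)))
    dxhat = dout * gamma
    dx = inv / D * (
        D * dxhat
        - dxhat.sum(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
    )
    return dx, dgamma, dbeta


def dense_forward(x, W, b):
    return x @ W + b, (x, W)


def dense_backward(dout, cache):
    x, W = cache
    dW = x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
    db = dout.reshape(-1, dout.shape[-1]).sum(axis=0)
    return dout @ W.T, dW, db


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def lstm_step_forward(x, h_prev, c_prev, Wx, Wh, b):
    """One LSTM step.  x: (B, D), h/c: (B, H), Wx: (D, 4H), Wh: (H, 4H)."""
    H = h_prev.shape[1]
    z = x @ Wx + h_prev @ Wh + b
    i = _sigmoid(z[:, :H])
    f = _sigmoid(z[:, H : 2 * H])
    g = np.tanh(z[:, 2 * H : 3 * H])
    o = _sigmoid(z[:, 3 * H :])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    return h, c, (x, h_prev, c_prev, i, f, g, o, tc, Wx, Wh)


def lstm_step_backward(dh, dc, cache):
    x, h_prev, c_prev, i, f, g, o, tc, Wx, Wh = cache
    do = dh * tc
    dc_total = dc + dh * o * (1.0 - tc * tc)
    di = dc_total * g
    df = dc_total * c_prev
    dg = dc_total * i
    dc_prev = dc_total * f
    dz = np.concatenate(
        [
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ],
        axis=1,
    )
    dWx = x.T @ dz
    dWh = h_prev.T @ dz
    db = dz.sum(axis=0)
    dx = dz @ Wx.T
    dh_prev = dz @ Wh.T
    return dx, dh_prev, dc_prev, dWx, dWh, db


def huber_loss(pred, target, delta=1.0, weights=None):
    """Mean Huber loss and its gradient w.r.t. ``pred``.

    ``weights`` (broadcastable to ``pred``) rescales elements, e.g. to
    emphasize late time steps of a sequence; it should average to ~1.
    """
    r = pred - target
    a = np.abs(r)
    quad = a <= delta
    loss = np.where(quad, 0.5 * r * r, delta * (a - 0.5 * delta))
    grad = np.where(quad, r, delta * np.sign(r)) / r.size
    if weights is not None:
        loss = loss * weights
        grad = grad * weights
    return float(loss.mean()), grad


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
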