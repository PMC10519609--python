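"""Minimal NumPy CNN stack: layers, Adam, and a sequential container.

Implements exactly what the compact atypia classifier needs — 3x3 and 1x1
convolutions (im2col), batch normalisation, ReLU, 2x2 max pooling, global
average pooling, a dense head and binary cross-entropy on logits — with
hand-written backward passes.  Everything is deterministic given the
`numpy.random.Generator` used for initialisation and shuffling.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2", "GlobalAvgPool", "Dense",
    "Sequential", "Adam", "bce_with_logits",
]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix, stride 1, same size."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    return win.reshape(n * h * w, c * k * k)


class Conv2d(Layer):
    """Stride-1 'same' convolution via im2col; no bias (BN follows)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.skip_input_grad = False  # set on the first layer: no one below
        fan_in = in_ch * k * k
        W = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k)).astype(np.float32)
        self.params = [W]
        self.grads = [np.zeros_like(W)]

    def forward(self, x, train):
        self._shape = x.shape
        n, c, h, w = x.shape
        pad = self.k // 2
        cols = _im2col(x, self.k, pad)
        self._cols = cols
        Wm = self.params[0].reshape(self.out_ch, -1)
        out = cols @ Wm.T
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, h, w = self._shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.grads[0][...] = (dmat.T @ self._cols).reshape(self.params[0].shape)
        if self.skip_input_grad:
            return dout
        # dx = 'full' conv of dout with the flipped, channel-swapped kernel
        W_flip = self.params[0][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        pad = self.k // 2
        cols_d = _im2col(dout, self.k, pad)
        Wm = W_flip.reshape(self.in_ch, -1)
        dx = cols_d @ Wm.T
        return dx.reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = [np.ones(ch, np.float32), np.zeros(ch, np.float32)]  # gamma, beta
        self.grads = [np.zeros(ch), np.zeros(ch)]
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x, train):
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return gamma[None, :, None, None] * xhat + beta[None, :, None, None]

    def backward(self, dout):
        gamma, _ = self.params
        xhat, inv, train, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.grads[0][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * gamma[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        t1 = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        t2 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (t1 - t2)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input H, W assumed even)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).copy()


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        W = rng.normal(0.0, math.sqrt(2.0 / in_dim), size=(in_dim, out_dim)).astype(np.float32)
        b = np.zeros(out_dim, np.float32)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers
        if layers and isinstance(layers[0], Conv2d):
            layers[0].skip_input_grad = True

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads))
        return out


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model, self.lr, self.betas, self.eps = model, lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.params_and_grads]
        self.v = [np.zeros_like(p) for p, _ in model.params_and_grads]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, (p, g) in enumerate(self.model.params_and_grads):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.ravel()
    y = y.astype(float).ravel()
    # stable log(1 + e^-|z|) formulation
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / len(z)).reshape(logits.shape)
    return loss, grad
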