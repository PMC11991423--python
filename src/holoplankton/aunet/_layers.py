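"""Minimal NumPy layers with explicit forward/backward passes.

Everything runs in float32 and is deterministic given the initializer
RNG, which makes training reproducible bit-for-bit on a fixed platform.
Tensors are laid out (batch, channels, rows, cols).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    params: list[np.ndarray] = []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict:
        """Extra non-trainable buffers to persist (overridden by BatchNorm)."""
        return {}

    def load_state(self, state: dict) -> None:
        pass


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (im2col + one matmul)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_out, c_in * 9)) * scale).astype(F32)
        self.b = np.zeros(c_out, F32)
        self.params = [self.W, self.b]

    def forward(self, x, train):
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        self._cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)
        self._shape = (b, c, h, w)
        y = self._cols @ self.W.T + self.b
        return y.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        b, c, h, w = self._shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(b * h * w, -1).astype(F32)
        self._gW = dyf.T @ self._cols
        self._gb = dyf.sum(axis=0)
        dcols = (dyf @ self.W).reshape(b, h, w, c, 3, 3)
        dxp = np.zeros((b, c, h + 2, w + 2), F32)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    @property
    def grads(self):
        return [self._gW, self._gb]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / c_in)
        self.W = (rng.standard_normal((c_out, c_in)) * scale).astype(F32)
        self.b = np.zeros(c_out, F32)
        self.params = [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        y = np.tensordot(x, self.W, axes=([1], [1])).transpose(0, 3, 1, 2)
        return (y + self.b[None, :, None, None]).astype(F32)

    def backward(self, dy):
        self._gW = np.tensordot(dy, self._x, axes=([0, 2, 3], [0, 2, 3])).astype(F32)
        self._gb = dy.sum(axis=(0, 2, 3)).astype(F32)
        return np.tensordot(dy, self.W, axes=([1], [0])).transpose(0, 3, 1, 2).astype(F32)

    @property
    def grads(self):
        return [self._gW, self._gb]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, F32)
        self.beta = np.zeros(channels, F32)
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(channels, F32)
        self.running_var = np.ones(channels, F32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._xhat = ((x - mean[None, :, None, None])
                      * self._istd[None, :, None, None]).astype(F32)
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        self._ggamma = (dy * self._xhat).sum(axis=(0, 2, 3)).astype(F32)
        self._gbeta = dy.sum(axis=(0, 2, 3)).astype(F32)
        dxhat = dy * self.gamma[None, :, None, None]
        # gradient through the batch statistics
        m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        return ((dxhat - m1 - self._xhat * m2)
                * self._istd[None, :, None, None]).astype(F32)

    @property
    def grads(self):
        return [self._ggamma, self._gbeta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        self.running_mean = state["running_mean"].astype(F32)
        self.running_var = state["running_var"].astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first position."""

    def forward(self, x, train):
        b, c, h, w = x.shape
        xr = (x.reshape(b, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4))
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, c, h, w = self._in_shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4), F32)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None].astype(F32), axis=-1)
        return (dxr.reshape(b, c, h // 2, w // 2, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w))


class ConvTranspose2(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 4))
        self.W = (rng.standard_normal((c_in, c_out, 2, 2)) * scale).astype(F32)
        self.b = np.zeros(c_out, F32)
        self.params = [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        b = x.shape[0]
        h, w = x.shape[2], x.shape[3]
        t = np.tensordot(x, self.W, axes=([1], [0]))  # b, h, w, c_out, 2, 2
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(b, self.W.shape[1], 2 * h, 2 * w)
        return (y + self.b[None, :, None, None]).astype(F32)

    def backward(self, dy):
        b, c_out, H, W = dy.shape
        t = (dy.reshape(b, c_out, H // 2, 2, W // 2, 2)
               .transpose(0, 2, 4, 1, 3, 5))  # b, h, w, c_out, 2, 2
        self._gW = np.tensordot(self._x, t, axes=([0, 2, 3], [0, 1, 2])).astype(F32)
        self._gb = dy.sum(axis=(0, 2, 3)).astype(F32)
        return np.tensordot(t, self.W, axes=([3, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2).astype(F32)

    @property
    def grads(self):
        return [self._gW, self._gb]


class Adam:
    """Standard Adam with bias correction, operating on a flat param list."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.dtype)
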