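"""Minimal 3D neural-network layers with forward/backward passes.

A compact NumPy engine sized for desk-scale volumes: 3D convolution is
implemented as im2col plus a BLAS matmul, pooling by reshape-and-reduce.
Tensors are NCDHW float32. Each layer exposes ``forward(x, training)``,
``backward(grad)``, and its parameter/gradient arrays for the optimizer.
Batch-normalization moving statistics are kept as (non-trainable) state so
parameter accounting matches the usual 4-per-channel convention.
"""

from __future__ import annotations

import numpy as np


class Layer:
    trainable: tuple[np.ndarray, ...] = ()
    gradients: tuple[np.ndarray, ...] = ()
    state: tuple[np.ndarray, ...] = ()          # counted but not optimized

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.trainable) + \
            sum(int(s.size) for s in self.state)


class Input(Layer):
    """Shape-checking identity layer."""

    def __init__(self, shape: tuple[int, int, int]):
        self.shape = tuple(shape)

    def forward(self, x, training):
        if x.shape[2:] != self.shape:
            raise ValueError(f"input spatial shape {x.shape[2:]} != {self.shape}")
        return x

    def backward(self, grad):
        return grad


class Conv3D(Layer):
    """3x3x3 (or kxkxk) same-padding, stride-1 convolution with ReLU."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int] = (3, 3, 3),
                 relu: bool = True, rng: np.random.Generator | None = None):
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("kernel dims must be odd for same padding")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.relu = relu
        fan_in = c_in * int(np.prod(kernel))
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((c_out, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.trainable = (self.W, self.b)
        self.gradients = (self.dW, self.db)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        kd, kh, kw = self.kernel
        pad = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in self.kernel]
        xp = np.pad(x, pad)
        cols = np.empty((n, c, kd * kh * kw, d, h, w), dtype=np.float32)
        i = 0
        for a in range(kd):
            for b in range(kh):
                for cc in range(kw):
                    cols[:, :, i] = xp[:, :, a:a + d, b:b + h, cc:cc + w]
                    i += 1
        return cols.reshape(n, c * kd * kh * kw, d * h * w)

    def forward(self, x, training):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._shape = x.shape
        self._cols = self._im2col(x)
        z = np.matmul(self.W, self._cols) + self.b[None, :, None]
        n, _, d, h, w = x.shape
        z = z.reshape(n, self.c_out, d, h, w)
        if self.relu:
            self._relu_mask = z > 0
            z = np.where(self._relu_mask, z, 0.0)
        return z

    def backward(self, grad):
        n, c, d, h, w = self._shape
        if self.relu:
            grad = np.where(self._relu_mask, grad, 0.0)
        g2 = grad.reshape(n, self.c_out, d * h * w)
        self.dW[...] = np.matmul(g2, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.db[...] = g2.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, g2)                 # (n, c_in*k3, dhw)
        kd, kh, kw = self.kernel
        dcols = dcols.reshape(n, c, kd * kh * kw, d, h, w)
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        gxp = np.zeros((n, c, d + 2 * pd, h + 2 * ph, w + 2 * pw), dtype=np.float32)
        i = 0
        for a in range(kd):
            for b in range(kh):
                for cc in range(kw):
                    gxp[:, :, a:a + d, b:b + h, cc:cc + w] += dcols[:, :, i]
                    i += 1
        self._cols = None
        return gxp[:, :, pd:pd + d, ph:ph + h, pw:pw + w]


class MaxPool3D(Layer):
    """2x2x2 max pooling with stride 2; odd trailing voxels are dropped
    (floor division), matching the usual valid-pooling convention."""

    def forward(self, x, training):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        if min(d2, h2, w2) < 1:
            raise ValueError(f"spatial shape {(d, h, w)} too small to pool")
        xc = x[:, :, :2 * d2, :2 * h2, :2 * w2]
        self._xc_shape = xc.shape
        self._in_shape = x.shape
        r = xc.reshape(n, c, d2, 2, h2, 2, w2, 2)
        out = r.max(axis=(3, 5, 7))
        expanded = np.repeat(np.repeat(np.repeat(out, 2, 2), 2, 3), 2, 4)
        self._mask = (xc == expanded)
        self._counts = self._mask.reshape(n, c, d2, 2, h2, 2, w2, 2).sum(axis=(3, 5, 7))
        return out

    def backward(self, grad):
        n, c, d2, h2, w2 = grad.shape
        g = grad / self._counts
        g = np.repeat(np.repeat(np.repeat(g, 2, 2), 2, 3), 2, 4)
        gx = np.zeros(self._in_shape, dtype=np.float32)
        gx[:, :, :2 * d2, :2 * h2, :2 * w2] = np.where(self._mask, g, 0.0)
        return gx


class BatchNorm3D(Layer):
    """Per-channel batch normalization (scale, shift + moving statistics)."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.moving_mean = np.zeros(channels, dtype=np.float32)
        self.moving_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.trainable = (self.gamma, self.beta)
        self.gradients = (self.dgamma, self.dbeta)
        self.state = (self.moving_mean, self.moving_var)

    def forward(self, x, training):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean[...] = self.momentum * self.moving_mean + (1 - self.momentum) * mean
            self.moving_var[...] = self.momentum * self.moving_var + (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        bshape = (1, -1, 1, 1, 1)
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean.reshape(bshape)) * self._inv_std.reshape(bshape)
        self._m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        self._training = training
        return self.gamma.reshape(bshape) * self._xhat + self.beta.reshape(bshape)

    def backward(self, grad):
        bshape = (1, -1, 1, 1, 1)
        axes = (0, 2, 3, 4)
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        gshaped = self.gamma.reshape(bshape) * self._inv_std.reshape(bshape)
        if not self._training:
            return grad * gshaped
        m = self._m
        dxhat = grad * self.gamma.reshape(bshape)
        t1 = dxhat - dxhat.mean(axis=axes).reshape(bshape)
        t2 = self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(bshape)
        return self._inv_std.reshape(bshape) * (t1 - t2)


class GlobalAvgPool3D(Layer):
    def forward(self, x, training):
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        d, h, w = self._spatial
        g = grad[:, :, None, None, None] / (d * h * w)
        return np.broadcast_to(g, grad.shape + self._spatial).astype(np.float32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str | None = "relu",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation
        self.trainable = (self.W, self.b)
        self.gradients = (self.dW, self.db)

    def forward(self, x, training):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        if self.activation == "sigmoid":
            self._out = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            return self._out
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = np.where(self._mask, grad, 0.0)
        elif self.activation == "sigmoid":
            grad = grad * self._out * (1.0 - self._out)
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0,1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask
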