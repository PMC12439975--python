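"""A compact, dependency-free neural-network engine (numpy, CPU).

Implements exactly the pieces the patch-expression predictor needs — 2D
convolution (im2col), batch normalization, ReLU, dropout, average pooling,
global average pooling, linear layers, MSE loss and the Adam optimizer — with
hand-written forward and backward passes. Every layer caches what its
backward pass needs; ``backward`` also works in inference mode (dropout as
identity, batchnorm via running statistics), which is what Grad-CAM uses to
obtain gradients with respect to convolutional feature maps.

Shapes follow the NCHW convention; parameters are float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "AvgPool2",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "mse_loss",
]


class Layer:
    """Base layer: ``forward(x, training)`` caches, ``backward(dy)`` returns dx."""

    def parameters(self):
        return []

    def forward(self, x, training: bool):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Conv2d(Layer):
    """3×3-style 'same' convolution via im2col, reflect padding, stride 1.

    Reflect padding avoids the frame artifacts zero padding imprints on
    small patches (which would otherwise dominate saliency maps of smooth
    images)."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, rng: np.random.Generator | None = None):
        if ksize % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * ksize * ksize
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, training):
        N, C, H, W = x.shape
        k, p = self.ksize, self.ksize // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (N, C, H, W, k, k) -> cols: (N*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)
        self._cols, self._shape = cols, (N, C, H, W)
        out = cols @ self.W.value.T + self.b.value
        return np.ascontiguousarray(
            out.reshape(N, H, W, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dy):
        N, C, H, W = self._shape
        k, p = self.ksize, self.ksize // 2
        dym = dy.transpose(0, 2, 3, 1).reshape(N * H * W, self.c_out)
        self.W.grad += dym.T @ self._cols
        self.b.grad += dym.sum(axis=0)
        dcols = (dym @ self.W.value).reshape(N, H, W, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        # fold reflected-border gradients back onto their source pixels
        tmp = dxp[:, :, :, p : p + W].copy()
        for d in range(1, p + 1):
            tmp[:, :, :, d] += dxp[:, :, :, p - d]
            tmp[:, :, :, W - 1 - d] += dxp[:, :, :, p + W - 1 + d]
        dx = tmp[:, :, p : p + H, :].copy()
        for d in range(1, p + 1):
            dx[:, :, d, :] += tmp[:, :, p - d, :]
            dx[:, :, H - 1 - d, :] += tmp[:, :, p + H - 1 + d, :]
        return dx


class BatchNorm(Layer):
    """Batch normalization over (N,) for 2D or (N, H, W) for 4D inputs."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def _axes_and_shape(self, x):
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        return (0,), (1, -1)

    def forward(self, x, training):
        axes, shape = self._axes_and_shape(x)
        self._training = training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._xhat, self._inv_std, self._axes, self._bshape = xhat, inv_std, axes, shape
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy):
        axes, shape = self._axes, self._bshape
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        if not self._training:
            return dy * g * self._inv_std.reshape(shape)
        n = dy.size // dy.shape[1] if dy.ndim == 4 else dy.shape[0]
        dxhat = dy * g
        term = (
            n * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True)
        )
        return term * self._inv_std.reshape(shape) / n


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class AvgPool2(Layer):
    """2×2 average pooling (even spatial dims required)."""

    def forward(self, x, training):
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("AvgPool2 needs even spatial dimensions")
        self._shape = x.shape
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        N, C, H, W = self._shape
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, training):
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._spatial
        return np.broadcast_to(dy[:, :, None, None], dy.shape + (h, w)).copy() / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.value
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff
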