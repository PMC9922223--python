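"""A small numpy neural-network engine for 3D volumes.

Implements exactly the layer set the diagnosis/severity networks need —
valid (unpadded, stride-1) 3D convolution, non-overlapping average/max
pooling, per-channel batch normalisation, dense layers, ReLU — with
reverse-mode gradients, an Adam optimiser, and the softmax cross-entropy /
mean-squared-error losses.  Data layout is (batch, channels, x, y, z) in
float32.  Convolution forward/backward are expressed as einsum contractions
over sliding-window views, so everything stays vectorised.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "AvgPool3d",
    "MaxPool3d",
    "BatchNorm3d",
    "Dense",
    "ReLU",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_with_logits",
    "mse_loss",
]


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """Valid (unpadded) stride-1 3D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel, kernel))
        self.w = w.astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.kernel
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        if train:
            self._win = win
        out = np.einsum("bcdhwijk,ocijk->bodhw", win, self.w, optimize=True)
        return (out + self.b[None, :, None, None, None]).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel
        self.grads[0][...] = np.einsum(
            "bcdhwijk,bodhw->ocijk", self._win, grad, optimize=True
        )
        self.grads[1][...] = grad.sum(axis=(0, 2, 3, 4))
        pad = [(0, 0), (0, 0)] + [(k - 1, k - 1)] * 3
        gpad = np.pad(grad, pad)
        gwin = sliding_window_view(gpad, (k, k, k), axis=(2, 3, 4))
        wflip = self.w[:, :, ::-1, ::-1, ::-1]
        dx = np.einsum("bodhwijk,ocijk->bcdhw", gwin, wflip, optimize=True)
        self._win = None
        return dx.astype(np.float32)


def _pool_reshape(x: np.ndarray, k: int) -> tuple[np.ndarray, tuple[int, ...]]:
    b, c, d, h, w = x.shape
    dp, hp, wp = d // k, h // k, w // k
    xr = x[:, :, : dp * k, : hp * k, : wp * k]
    xr = xr.reshape(b, c, dp, k, hp, k, wp, k)
    return xr, (b, c, dp, hp, wp)


class AvgPool3d(Layer):
    """Non-overlapping average pooling (kernel 1 is a pass-through slot)."""

    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.kernel == 1:
            return x
        self._in_shape = x.shape
        xr, _ = _pool_reshape(x, self.kernel)
        return xr.mean(axis=(3, 5, 7))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel
        if k == 1:
            return grad
        dx = np.zeros(self._in_shape, dtype=np.float32)
        b, c, dp, hp, wp = grad.shape
        g = (grad / k**3)[:, :, :, None, :, None, :, None]
        dx[:, :, : dp * k, : hp * k, : wp * k] = np.broadcast_to(
            g, (b, c, dp, k, hp, k, wp, k)
        ).reshape(b, c, dp * k, hp * k, wp * k)
        return dx


class MaxPool3d(Layer):
    """Non-overlapping max pooling; gradient routed to the arg-max voxel."""

    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.kernel == 1:
            return x
        self._in_shape = x.shape
        xr, out_shape = _pool_reshape(x, self.kernel)
        k = self.kernel
        flat = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(*out_shape, k**3)
        if train:
            self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel
        if k == 1:
            return grad
        b, c, dp, hp, wp = grad.shape
        flat = np.zeros((b, c, dp, hp, wp, k**3), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        blocks = flat.reshape(b, c, dp, hp, wp, k, k, k).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        )
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, : dp * k, : hp * k, : wp * k] = blocks.reshape(
            b, c, dp * k, hp * k, wp * k
        )
        self._argmax = None
        return dx


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over (batch, x, y, z) with learned
    scale/shift and running statistics for evaluation mode."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var[...] = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._xhat, self._inv, self._n = xhat, inv, x[:, 0].size
        return (self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)).astype(
            np.float32
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        n = self._n
        g = grad * self.gamma.reshape(shape)
        dx = (
            g
            - g.mean(axis=axes).reshape(shape)
            - self._xhat * (g * self._xhat).mean(axis=axes).reshape(shape)
        ) * self._inv.reshape(shape)
        self._xhat = self._inv = None
        return dx.astype(np.float32)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim)).astype(
            np.float32
        )
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = grad * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential:
    """A plain layer stack with weight snapshot/restore for early stopping."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads))
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the model state (weights + BN running stats)."""
        arrays = []
        for layer in self.layers:
            arrays.extend(layer.params)
            if isinstance(layer, BatchNorm3d):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def get_weights(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(weights):
            raise ValueError("weight list does not match model structure")
        for dst, src in zip(arrays, weights):
            dst[...] = src


class Adam:
    """Adaptive moment estimation optimiser."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_logits(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    b = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / b)
    return loss, ((p - onehot) / b).astype(np.float32)

def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. the predictions."""
    diff = pred - target
    b = pred.shape[0]
    loss = float((diff**2).sum() / pred.size)
    return loss, (2.0 * diff / pred.size).astype(np.float32)
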