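"""Compact numpy neural-network engine (NCHW, float32).

Implements exactly the layer families the identification network needs —
convolution (im2col + BLAS matmul), batch normalization, ReLU, max pooling,
global average pooling, fully connected layers, squeeze-and-excitation
attention, and the residual BasicBlock — each with a hand-written backward
pass, plus SGD with momentum, Glorot (Xavier) initialization and a
numerically stable cross-entropy loss.

Every layer caches what its backward pass needs during ``forward(train=True)``;
inference with ``train=False`` caches nothing and uses BN running statistics.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .model_zoo import ShapeError

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "SEBlock",
    "BasicBlock",
    "MultiScale",
    "Sequential",
    "SGD",
    "softmax",
    "cross_entropy",
    "xavier_init",
]

_F32 = np.float32


class Layer:
    """Base layer: named parameter/gradient pairs and forward/backward."""

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        return []

    def gradients(self) -> list[tuple[str, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, Ho, Wo, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def _col2im(
    dcol: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    """Scatter-add patch gradients back to the (padded) input."""
    n, c, h, w = x_shape
    ho, wo = dcol.shape[1], dcol.shape[2]
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    # (N, Ho, Wo, C, k, k) -> (N, C, Ho, Wo, k, k)
    d = dcol.transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += d[
                :, :, :, :, ki, kj
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = False):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.W = np.zeros((out_channels, in_channels, kernel, kernel), dtype=_F32)
        self.b = np.zeros(out_channels, dtype=_F32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    def parameters(self):
        p = [("W", self.W)]
        if self.b is not None:
            p.append(("b", self.b))
        return p

    def gradients(self):
        g = [("W", self.dW)]
        if self.b is not None:
            g.append(("b", self.db))
        return g

    def forward(self, x, train=False):
        if x.shape[1] != self.in_channels:
            raise ShapeError(
                f"conv expects {self.in_channels} channels, got {x.shape[1]}"
            )
        cols = _im2col(x, self.kernel, self.stride, self.padding)
        n, ho, wo = cols.shape[:3]
        flat = cols.reshape(n * ho * wo, -1)
        out = flat @ self.W.reshape(self.out_channels, -1).T
        if self.b is not None:
            out += self.b
        out = out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)
        if train:
            self._cache = (flat, x.shape, (n, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, grad):
        flat, x_shape, (n, ho, wo) = self._cache
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_channels)
        self.dW[...] = (g.T @ flat).reshape(self.W.shape)
        if self.b is not None:
            self.db[...] = g.sum(axis=0)
        dflat = g @ self.W.reshape(self.out_channels, -1)
        dcol = dflat.reshape(n, ho, wo, self.in_channels, self.kernel, self.kernel)
        self._cache = None
        return _col2im(dcol, x_shape, self.kernel, self.stride, self.padding)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self._cache = None

    def parameters(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def gradients(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return out.astype(_F32, copy=False)

    def backward(self, grad):
        xhat, inv = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * inv[None, :, None, None]
        return dx.astype(_F32, copy=False)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.padding
        xp = x
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                        constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, xp.shape)
        return np.ascontiguousarray(out.astype(_F32, copy=False))

    def backward(self, grad):
        idx, x_shape, xp_shape = self._cache
        self._cache = None
        k, s, p = self.kernel, self.stride, self.padding
        n, c, ho, wo = grad.shape
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        ki, kj = idx // k, idx % k
        rows = (np.arange(ho)[None, None, :, None] * s + ki)
        cols = (np.arange(wo)[None, None, None, :] * s + kj)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, cols), grad)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def __init__(self):
        self._hw = None

    def forward(self, x, train=False):
        if train:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        h, w = self._hw
        self._hw = None
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), grad.shape + (h, w)
        ).astype(_F32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.W = np.zeros((out_features, in_features), dtype=_F32)
        self.b = np.zeros(out_features, dtype=_F32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x = None

    def parameters(self):
        p = [("W", self.W)]
        if self.b is not None:
            p.append(("b", self.b))
        return p

    def gradients(self):
        g = [("W", self.dW)]
        if self.b is not None:
            g.append(("b", self.db))
        return g

    def forward(self, x, train=False):
        out = x @ self.W.T
        if self.b is not None:
            out = out + self.b
        if train:
            self._x = x
        return out

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        if self.b is not None:
            self.db[...] = grad.sum(axis=0)
        dx = grad @ self.W
        self._x = None
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SEBlock(Layer):
    """Squeeze-and-excitation: GAP -> FC(C->b) -> ReLU -> FC(b->C) -> sigmoid,
    then per-channel rescaling of the input feature map.

    Sigmoid outputs lie strictly in (0, 1) for finite logits, so the block
    attenuates but never zeroes or amplifies a channel.
    """

    def __init__(self, channels: int, reduction_ratio: int = 16):
        self.channels = channels
        self.reduction_ratio = reduction_ratio
        b = max(1, channels // reduction_ratio)
        self.bottleneck = b
        self.fc1 = Linear(channels, b)
        self.fc2 = Linear(b, channels)
        self._cache = None

    def parameters(self):
        return [("fc1." + n, p) for n, p in self.fc1.parameters()] + [
            ("fc2." + n, p) for n, p in self.fc2.parameters()
        ]

    def gradients(self):
        return [("fc1." + n, g) for n, g in self.fc1.gradients()] + [
            ("fc2." + n, g) for n, g in self.fc2.gradients()
        ]

    def excitation(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Channel scales in (0,1) for an (N,C,H,W) input."""
        s = x.mean(axis=(2, 3))  # squeeze
        h = self.fc1.forward(s, train)
        hr = np.maximum(h, 0)
        z = self.fc2.forward(hr, train)
        e = _sigmoid(z)
        if train:
            self._ex_cache = (h, e)
        return e

    def forward(self, x, train=False):
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ShapeError(
                f"SE block expects (N,{self.channels},H,W), got {x.shape}"
            )
        e = self.excitation(x, train)
        out = x * e[:, :, None, None]
        if train:
            self._cache = (x, e, x.shape[2:], self._ex_cache)
        return out

    def backward(self, grad):
        x, e, (hgt, wid), (h, _e) = self._cache
        self._cache = None
        dx_direct = grad * e[:, :, None, None]
        de = (grad * x).sum(axis=(2, 3))
        dz = de * e * (1.0 - e)
        dhr = self.fc2.backward(dz)
        dh = dhr * (h > 0)
        ds = self.fc1.backward(dh)
        dx_squeeze = ds[:, :, None, None] / (hgt * wid)
        return (dx_direct + dx_squeeze).astype(_F32, copy=False)


class Sequential(Layer):
    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers

    def parameters(self):
        out = []
        for name, layer in self.layers:
            out += [(f"{name}.{n}", p) for n, p in layer.parameters()]
        return out

    def gradients(self):
        out = []
        for name, layer in self.layers:
            out += [(f"{name}.{n}", g) for n, g in layer.gradients()]
        return out

    def forward(self, x, train=False):
        for _, layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class MultiScale(Layer):
    """Four parallel conv+BN+ReLU branches merged by depth concatenation."""

    def __init__(self, in_channels: int, branch_widths, kernels=(7, 5, 3, 1)):
        self.in_channels = in_channels
        self.branch_widths = tuple(branch_widths)
        self.branches = []
        for k, w in zip(kernels, self.branch_widths):
            self.branches.append(
                Sequential([
                    ("conv", Conv2d(in_channels, w, k, stride=1, padding=k // 2)),
                    ("bn", BatchNorm2d(w)),
                    ("relu", ReLU()),
                ])
            )
        self._kernels = kernels

    def parameters(self):
        out = []
        for k, br in zip(self._kernels, self.branches):
            out += [(f"b{k}x{k}.{n}", p) for n, p in br.parameters()]
        return out

    def gradients(self):
        out = []
        for k, br in zip(self._kernels, self.branches):
            out += [(f"b{k}x{k}.{n}", g) for n, g in br.gradients()]
        return out

    def forward(self, x, train=False):
        return np.concatenate([br.forward(x, train) for br in self.branches], axis=1)

    def backward(self, grad):
        splits = np.cumsum(self.branch_widths)[:-1]
        parts = np.split(grad, splits, axis=1)
        dx = None
        for br, g in zip(self.branches, parts):
            d = br.backward(np.ascontiguousarray(g))
            dx = d if dx is None else dx + d
        return dx


class BasicBlock(Layer):
    """relu(x + bn2(conv2(relu(bn1(conv1(x)))))), channels preserved."""

    def __init__(self, channels: int):
        self.channels = channels
        self.conv1 = Conv2d(channels, channels, 3, padding=1)
        self.bn1 = BatchNorm2d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, padding=1)
        self.bn2 = BatchNorm2d(channels)
        self._mask = None

    def _subs(self):
        return [("conv1", self.conv1), ("bn1", self.bn1),
                ("conv2", self.conv2), ("bn2", self.bn2)]

    def parameters(self):
        out = []
        for name, layer in self._subs():
            out += [(f"{name}.{n}", p) for n, p in layer.parameters()]
        return out

    def gradients(self):
        out = []
        for name, layer in self._subs():
            out += [(f"{name}.{n}", g) for n, g in layer.gradients()]
        return out

    def forward(self, x, train=False):
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ShapeError(
                f"BasicBlock expects (N,{self.channels},H,W), got {x.shape}"
            )
        r = self.conv1.forward(x, train)
        r = self.bn1.forward(r, train)
        r = self.relu1.forward(r, train)
        r = self.conv2.forward(r, train)
        r = self.bn2.forward(r, train)
        pre = x + r
        out = np.maximum(pre, 0)
        if train:
            self._mask = pre > 0
        return out

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        dr = self.bn2.backward(g)
        dr = self.conv2.backward(dr)
        dr = self.relu1.backward(dr)
        dr = self.bn1.backward(dr)
        dr = self.conv1.backward(dr)
        return g + dr


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[tuple[str, np.ndarray]],
                 grads: list[tuple[str, np.ndarray]],
                 lr: float = 0.01, momentum: float = 0.9):
        assert [n for n, _ in params] == [n for n, _ in grads]
        self.params = [p for _, p in params]
        self.grads = [g for _, g in grads]
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in self.params]

    def step(self) -> None:
        for p, g, v in zip(self.params, self.grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()
    dlogits = softmax(logits)
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(_F32)


def xavier_init(model: Layer, seed: int) -> Layer:
    """Glorot-normal weights (variance 2/(fan_in+fan_out)), zero biases,
    unit BN scales and zero BN shifts; deterministic under ``seed``.

    Walks the model's named parameters in definition order so the draw
    sequence — and therefore the initialization — is reproducible.
    """
    rng = np.random.default_rng(seed)
    for layer in _walk_layers(model):
        if isinstance(layer, (Conv2d, Linear)):
            if isinstance(layer, Conv2d):
                k2 = layer.kernel**2
                fan_in = layer.in_channels * k2
                fan_out = layer.out_channels * k2
            else:
                fan_in, fan_out = layer.in_features, layer.out_features
            std = np.sqrt(2.0 / (fan_in + fan_out))
            layer.W[...] = rng.normal(0.0, std, size=layer.W.shape).astype(_F32)
            if layer.b is not None:
                layer.b[...] = 0.0
        elif isinstance(layer, BatchNorm2d):
            layer.gamma[...] = 1.0
            layer.beta[...] = 0.0
            layer.running_mean[...] = 0.0
            layer.running_var[...] = 1.0
    return model


def _walk_layers(layer: Layer):
    """Depth-first traversal over primitive layers, in definition order."""
    if isinstance(layer, Sequential):
        for _, sub in layer.layers:
            yield from _walk_layers(sub)
    elif isinstance(layer, MultiScale):
        for br in layer.branches:
            yield from _walk_layers(br)
    elif isinstance(layer, SEBlock):
        yield layer.fc1
        yield layer.fc2
    elif isinstance(layer, BasicBlock):
        for _, sub in layer._subs():
            yield from _walk_layers(sub)
    else:
        yield layer
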