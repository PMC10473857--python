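"""Minimal CNN building blocks on numpy: layers, backprop and Adam.

Implements exactly what the grain classifiers need — 2-D convolution (via
im2col and BLAS matmul), batch normalization, ReLU, max/average pooling,
fully-connected layers, bottleneck residual blocks with identity or
projection shortcuts, softmax cross-entropy, and the Adam optimizer.
Everything runs in float32 on the CPU and is deterministic given the
numpy Generator used for initialization and batching.

Tensors are NCHW.  He-normal initialization for convolutions and linear
layers.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value.astype(np.float32)
        self.g = np.zeros_like(self.v)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """k x k convolution, stride ``s``, symmetric zero padding ``pad``."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = True):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.W = Param(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch)) if bias else None
        self._cache = None

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo]  # (N, C, ho, wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, self.in_ch * k * k)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x, train):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, ho, wo)
        wmat = self.W.v.reshape(self.out_ch, -1)
        y = cols @ wmat.T
        if self.b is not None:
            y += self.b.v
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dy2 = dy.transpose(0, 2, 3, 1).reshape(-1, self.out_ch).astype(np.float32)
        self.W.g += (dy2.T @ cols).reshape(self.W.v.shape)
        if self.b is not None:
            self.b.g += dy2.sum(axis=0)
        dcols = (dy2 @ self.W.v.reshape(self.out_ch, -1))
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    ``bypass=True`` turns the layer into an exact identity (used to verify
    the residual identity property without the epsilon in the variance).
    """

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.bypass = False
        self._cache = None

    def forward(self, x, train):
        if self.bypass:
            self._cache = None
            return x
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, dy):
        if self.bypass:
            return dy
        xhat, inv, train = self._cache
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.v[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, :, : ho * 2, : wo * 2]
        blocks = xc.reshape(n, c, ho, 2, wo, 2)
        y = blocks.max(axis=(3, 5))
        self._cache = (x.shape, blocks, y)
        return y

    def backward(self, dy):
        xshape, blocks, y = self._cache
        n, c, h, w = xshape
        ho, wo = h // 2, w // 2
        mask = blocks == y[:, :, :, None, :, None]
        # distribute to the first max in each block to keep gradients exact
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        first = np.cumsum(flat, axis=-1) == 1
        flat = flat & first
        mask = flat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(xshape, dtype=np.float32)
        dx[:, :, : ho * 2, : wo * 2] = (
            mask * dy[:, :, :, None, :, None]
        ).reshape(n, c, ho * 2, wo * 2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(
            dy[:, :, None, None] / (h * w), self._shape
        ).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_f)
        self.W = Param(rng.normal(0.0, std, size=(in_f, out_f)))
        self.b = Param(np.zeros(out_f))

    def forward(self, x, train):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy):
        self.W.g += self._x.T @ dy
        self.b.g += dy.sum(axis=0)
        return (dy @ self.W.v.T).astype(np.float32)

    def params(self):
        return [self.W, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Bottleneck(Layer):
    """Residual bottleneck: ``Y = relu(F(X) + shortcut(X))``.

    ``F`` is 1x1 -> 3x3 (stride) -> 1x1 convolutions, each batch-normalized;
    the shortcut is the identity (``projection=False``; requires matching
    shapes) or a learned 1x1 projection with batch norm.
    """

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int,
                 rng: np.random.Generator, stride: int = 1,
                 projection: bool = False):
        if not projection and (in_ch != out_ch or stride != 1):
            raise ValueError("identity shortcut requires matching shapes")
        self.projection = projection
        self.conv1 = Conv2d(in_ch, mid_ch, 1, rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, rng, stride=stride)
        self.bn2 = BatchNorm2d(mid_ch)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, rng)
        self.bn3 = BatchNorm2d(out_ch)
        self.relu1, self.relu2, self.relu_out = ReLU(), ReLU(), ReLU()
        if projection:
            self.proj = Conv2d(in_ch, out_ch, 1, rng, stride=stride, pad=0)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = self.proj_bn = None

    def residual_layers(self) -> list[Layer]:
        return [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]

    def forward(self, x, train):
        f = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        f = self.relu2.forward(self.bn2.forward(self.conv2.forward(f, train), train), train)
        f = self.bn3.forward(self.conv3.forward(f, train), train)
        if self.projection:
            sc = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(f + sc, train)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        df = self.bn3.backward(dsum)
        df = self.conv3.backward(df)
        df = self.relu2.backward(df)
        df = self.conv2.backward(self.bn2.backward(df))
        df = self.relu1.backward(df)
        dx = self.conv1.backward(self.bn1.backward(df))
        if self.projection:
            dx = dx + self.proj.backward(self.proj_bn.backward(dsum))
        else:
            dx = dx + dsum
        return dx

    def params(self):
        ps = []
        for layer in self.residual_layers():
            ps.extend(layer.params())
        if self.projection:
            ps.extend(self.proj.params())
            ps.extend(self.proj_bn.params())
        return ps


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.g.fill(0.0)

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m *= self.b1
            m += (1 - self.b1) * p.g
            s *= self.b2
            s += (1 - self.b2) * p.g ** 2
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)
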