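"""Minimal CPU neural-network engine used by the enhancement and quantification nets.

Layers operate on float32 arrays in NHWC layout (channels last, so im2col and
1x1 convolutions reduce to contiguous copies and BLAS GEMMs) and implement
explicit forward/backward passes. Randomness is confined to the
``numpy.random.Generator`` passed at construction, which makes seeded training
runs repeatable on a fixed backend/thread configuration.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Workspace:
    """Per-layer scratch buffers, reused across steps to avoid large
    allocate/free cycles (which otherwise dominate conv runtime via page
    faults)."""

    __slots__ = ("_bufs",)

    def __init__(self):
        self._bufs: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple[int, ...], zero: bool = False) -> np.ndarray:
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape:
            buf = np.zeros(shape, dtype=F32) if zero else np.empty(shape, dtype=F32)
            self._bufs[name] = buf
        elif zero:
            buf.fill(0.0)
        return buf


def _im2col3(x: np.ndarray, ws: _Workspace, name: str = "cols") -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, 9*C) patch matrix for a 3x3 same-padded conv."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = ws.get(name, (n, h, w, 9, c))
    for a in range(3):
        for b in range(3):
            cols[:, :, :, 3 * a + b, :] = xp[:, a : a + h, b : b + w, :]
    return cols.reshape(n * h * w, 9 * c)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding. He-normal init.

    Weight layout: (cout, 9*cin) with the 3x3 offset major and input channel
    minor, matching the im2col column order.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        scale = np.sqrt(2.0 / (cin * 9))
        self.w = Param(rng.normal(0.0, scale, (cout, cin * 9)))
        self.b = Param(np.zeros(cout))
        self._ws = _Workspace()

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        cols = _im2col3(x, self._ws)
        if train:
            self._cols, self._shape = cols, x.shape
        y = self._ws.get("y", (n * h * w, self.cout))
        np.matmul(cols, self.w.value.T, out=y)
        y += self.b.value
        return y.reshape(n, h, w, self.cout).copy()

    def backward(self, dy):
        n, h, w, c = self._shape
        dyf = dy.reshape(n * h * w, self.cout)
        self.w.grad += dyf.T @ self._cols
        self.b.grad += dyf.sum(axis=0)
        dcols = self._ws.get("dcols", (n * h * w, 9 * c))
        np.matmul(dyf, self.w.value, out=dcols)
        dcols = dcols.reshape(n, h, w, 9, c)
        dxp = self._ws.get("dxp", (n, h + 2, w + 2, c), zero=True)
        for a in range(3):
            for b in range(3):
                dxp[:, a : a + h, b : b + w, :] += dcols[:, :, :, 3 * a + b, :]
        return dxp[:, 1 : h + 1, 1 : w + 1, :].copy()


class Conv1x1(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (cout, cin)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        n, h, w, _ = dy.shape
        dyf = dy.reshape(-1, self.cout)
        self.w.grad += dyf.T @ self._x.reshape(-1, self.cin)
        self.b.grad += dyf.sum(axis=0)
        return dy @ self.w.value


class ConvTranspose2x2(Layer):
    """2x2 transpose convolution with stride 2 (doubles H and W)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        scale = np.sqrt(2.0 / (cin * 4))
        self.w = Param(rng.normal(0.0, scale, (4, cin, cout)))  # (2x2 offset, cin, cout)
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        n, h, w, c = x.shape
        xf = x.reshape(-1, c)
        y = np.empty((n, h, 2, w, 2, self.cout), dtype=F32)
        for a in range(2):
            for b in range(2):
                y[:, :, a, :, b, :] = (xf @ self.w.value[2 * a + b]).reshape(n, h, w, self.cout)
        return y.reshape(n, 2 * h, 2 * w, self.cout) + self.b.value

    def backward(self, dy):
        n, h2, w2, _ = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(n, h, 2, w, 2, self.cout)
        xf = self._x.reshape(-1, self.cin)
        dx = np.zeros((n * h * w, self.cin), dtype=F32)
        for a in range(2):
            for b in range(2):
                dyf = np.ascontiguousarray(dyb[:, :, a, :, b, :]).reshape(-1, self.cout)
                self.w.grad[2 * a + b] += xf.T @ dyf
                dx += dyf @ self.w.value[2 * a + b].T
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return dx.reshape(n, h, w, self.cin)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
            self._inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
            self._xhat = (x - mean) * self._inv
            return self.gamma.value * self._xhat + self.beta.value
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * self._xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        t1 = dxhat.sum(axis=(0, 1, 2))
        t2 = (dxhat * self._xhat).sum(axis=(0, 1, 2))
        dx = (self._inv / m) * (m * dxhat - t1 - self._xhat * t2)
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y.astype(F32)

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2x2(Layer):
    def forward(self, x, train=True):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        if train:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._shape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    """(N,H,W,C) -> (N,C): each feature map collapses to its mean."""

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).astype(F32)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (cout, cin)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# -- losses ------------------------------------------------------------------

def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff.astype(F32)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff).astype(F32) / diff.size


# -- weight (de)serialization ------------------------------------------------

def get_weights(model: Layer) -> list[np.ndarray]:
    out = [p.value.copy() for p in model.params()]
    for l in _iter_layers(model):
        if isinstance(l, BatchNorm2d):
            out.append(l.running_mean.copy())
            out.append(l.running_var.copy())
    return out


def set_weights(model: Layer, weights: list[np.ndarray]) -> None:
    params = model.params()
    bns = [l for l in _iter_layers(model) if isinstance(l, BatchNorm2d)]
    expected = len(params) + 2 * len(bns)
    if len(weights) != expected:
        raise ValueError(f"weight list has {len(weights)} arrays, model expects {expected}")
    i = 0
    for p in params:
        if p.value.shape != weights[i].shape:
            raise ValueError(f"shape mismatch at tensor {i}: {p.value.shape} vs {weights[i].shape}")
        p.value = np.ascontiguousarray(weights[i], dtype=F32)
        i += 1
    for l in bns:
        l.running_mean = np.ascontiguousarray(weights[i], dtype=F32)
        l.running_var = np.ascontiguousarray(weights[i + 1], dtype=F32)
        i += 2


def _iter_layers(model: Layer):
    if isinstance(model, Sequential):
        for l in model.layers:
            yield from _iter_layers(l)
    elif hasattr(model, "sublayers"):
        for l in model.sublayers():
            yield from _iter_layers(l)
    else:
        yield model
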