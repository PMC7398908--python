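"""Minimal CPU neural-network engine (numpy, manual backprop).

Just enough machinery for the compact convolutional detectors and
single-cell graders in this package: im2col convolution, batch
normalization, ReLU, linear layers, global average pooling, a Sequential
container and Adam.  Layout is NCHW float32.  Every layer caches what its
backward pass needs from the latest forward call, so forward/backward pairs
must not be interleaved across batches.  Gradient correctness is pinned by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batchnorm running stats), in order."""
        return []

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        return self

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Module):
    """k x k convolution via im2col; He-normal init."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if pad is None:
            pad = k // 2
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, cin, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, ho * wo, cin * k * k
        )
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(n, self.cout, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        n, cin, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dflat = np.ascontiguousarray(
            dout.reshape(n, self.cout, ho * wo).transpose(0, 2, 1), dtype=np.float32
        )
        self.w.grad += np.einsum("nlc,nlk->ck", dflat, cols, optimize=True)
        self.b.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ self.w.value  # (n, L, cin*k*k)
        dcols = dcols.reshape(n, ho, wo, cin, k, k)
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not self.training:
            return dxhat * inv_std[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class GlobalAvgPool2d(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / nin)
        self.w = Param(rng.normal(0.0, scale, size=(nout, nin)))
        self.b = Param(np.zeros(nout))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = np.ascontiguousarray(x, dtype=np.float32)
        return self._x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout.astype(np.float32, copy=False)
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def params(self) -> list[Param]:
        return [p for m in self.modules for p in m.params()]

    def train(self, mode: bool = True) -> "Sequential":
        self.training = mode
        for m in self.modules:
            m.train(mode)
        return self

    def buffers(self) -> list[np.ndarray]:
        return [b for m in self.modules for b in m.buffers()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout


def conv_block(cin: int, cout: int, stride: int, rng: np.random.Generator) -> Sequential:
    """conv3x3(stride) -> batchnorm -> ReLU."""
    return Sequential(Conv2d(cin, cout, 3, stride=stride, rng=rng),
                      BatchNorm2d(cout), ReLU())


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bias1 = 1.0 - self.b1 ** self.t
        bias2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def cosine_lr(max_lr: float, epoch: int, total_epochs: int, floor: float = 0.01) -> float:
    """Cosine decay from max_lr to floor*max_lr over the epoch schedule."""
    if total_epochs <= 1:
        return max_lr
    frac = epoch / (total_epochs - 1)
    return max_lr * (floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * frac)))
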