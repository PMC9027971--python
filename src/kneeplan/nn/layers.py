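"""Minimal NumPy layers with hand-written backpropagation.

Only what the hourglass detection network needs: 2D convolution (stride 1,
same padding via im2col + BLAS), batch normalization, ReLU, 2x2 max pooling,
nearest-neighbour 2x upsampling and a sigmoid. Each layer caches what its
backward pass requires; parameters are :class:`Param` objects holding data
and an accumulated gradient.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np


class Param:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: parameter discovery walks attributes recursively."""

    train_mode: bool = True

    def parameters(self) -> Iterator[Param]:
        seen: set[int] = set()
        yield from self._walk(self, seen)

    @staticmethod
    def _walk(obj, seen: set[int]) -> Iterator[Param]:
        for value in vars(obj).values():
            if isinstance(value, Param) and id(value) not in seen:
                seen.add(id(value))
                yield value
            elif isinstance(value, Module) and id(value) not in seen:
                seen.add(id(value))
                yield from Module._walk(value, seen)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module) and id(item) not in seen:
                        seen.add(id(item))
                        yield from Module._walk(item, seen)

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def set_train(self, mode: bool) -> None:
        for m in self.modules():
            m.train_mode = mode

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(arrays):
            raise ValueError(f"state mismatch: {len(params)} params vs {len(arrays)} arrays")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch for {p.name}: {p.data.shape} vs {a.shape}")
            p.data[...] = a


class Conv2d(Module):
    """Stride-1 convolution with 'same' zero padding for odd kernels."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, bias: bool = True) -> None:
        fan_in = cin * k * k
        std = math.sqrt(2.0 / fan_in)
        self.k = k
        self.pad = k // 2
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k)), name=f"conv{k}x{k}.W")
        self.b = Param(np.zeros(cout), name=f"conv{k}x{k}.b") if bias else None
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (N, C, H, W, k, k) -> cols (N*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        wmat = self.W.data.reshape(self.W.data.shape[0], -1)
        y = cols @ wmat.T
        if self.b is not None:
            y += self.b.data
        self._cols = cols
        self._xshape = x.shape
        return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, cout, h, w = dy.shape
        k, p = self.k, self.pad
        cin = self._xshape[1]
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        self.W.grad += (dy_mat.T @ self._cols).reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad += dy_mat.sum(axis=0)
        dcols = dy_mat @ self.W.data.reshape(cout, -1)  # (N*H*W, C*k*k)
        dcols = dcols.reshape(n, h, w, cin, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(c), name="bn.gamma")
        self.beta = Param(np.zeros(c), name="bn.beta")
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        if not self.train_mode:
            return dy * (self.gamma.data * inv_std)[None, :, None, None]
        g = self.gamma.data[None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std[None, :, None, None]
        return dx


class ReLU(Module):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Module):
    """2x2 max pooling, stride 2 (inputs must have even spatial size)."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._idx = idx
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sigmoid(Module):
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        return dy * y * (1.0 - y)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
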