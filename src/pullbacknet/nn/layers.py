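"""Minimal feed-forward layers with explicit backpropagation.

Every module follows the same contract: ``forward(x)`` caches whatever the
matching ``backward(dout)`` call needs, ``backward`` accumulates parameter
gradients into ``Param.grad`` and returns the gradient with respect to the
module input.  One ``forward`` is paired with at most one ``backward``.

Convolutions are evaluated as a single matrix product over im2col patches,
which keeps the arithmetic inside BLAS even for small images.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: child modules and parameters are discovered by attribute walk."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for attr in self.__dict__.values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """2-D convolution (cross-correlation) over NCHW tensors."""

    def __init__(self, cin: int, cout: int, ksize: int, stride: int = 1,
                 padding: int = 0, *, rng: np.random.Generator, dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, ksize
        self.stride, self.padding = stride, padding
        fan_in = cin * ksize * ksize
        self.W = Param("W", he_normal(rng, (cout, fan_in), fan_in, dtype))
        self.b = Param("b", np.zeros(cout, dtype=dtype))
        self._cache = None

    def out_shape(self, H: int, W: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.padding
        return (H + 2 * p - k) // s + 1, (W + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        k, s, p = self.k, self.stride, self.padding
        OH, OW = self.out_shape(H, W)
        if OH < 1 or OW < 1:
            raise ValueError(f"spatial size {H}x{W} too small for kernel {k} stride {s}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # (N, C, OH, OW, k, k) view, strided by s
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * OH * OW, C * k * k)
        out = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape, xp.shape, OH, OW)
        return out.reshape(N, OH, OW, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, OH, OW = self._cache
        N, C, H, W = x_shape
        k, s, p = self.k, self.stride, self.padding
        d = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.W.grad += d.T @ cols
        self.b.grad += d.sum(axis=0)
        dcols = (d @ self.W.value).reshape(N, OH, OW, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += dcols[:, :, :, :, i, j]
        self._cache = None
        return dxp[:, :, p:p + H, p:p + W] if p else dxp


class Linear(Module):
    def __init__(self, nin: int, nout: int, *, rng: np.random.Generator, dtype=np.float32):
        self.W = Param("W", he_normal(rng, (nout, nin), nin, dtype))
        self.b = Param("b", np.zeros(nout, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        self._x = None
        return dout @ self.W.value


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._mask
        self._mask = None
        return out


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W)


class BasicBlock(Module):
    """Residual pair of 3x3 convolutions with identity or projection shortcut."""

    def __init__(self, cin: int, cout: int, stride: int, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, padding=1, rng=rng, dtype=dtype)
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, padding=0, rng=rng, dtype=dtype)
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(h + s)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        dx = dx + (self.proj.backward(d) if self.proj is not None else d)
        return dx
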