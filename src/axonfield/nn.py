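"""Minimal 3D convolutional network stack (numpy, CPU).

Define-by-layer modules with explicit ``forward``/``backward`` passes and an
Adam optimizer — enough to express and train the 3D U-Net used for
distance-field regression.  Tensors are channel-first ``(C, D, H, W)``
float32 with an implicit batch of one (the training protocol uses batch
size 1).  All backward passes are validated against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "Conv1x1",
    "ConvTranspose3d2x",
    "LeakyReLU",
    "InstanceNorm",
    "MaxPool2",
    "Adam",
]

_OFFSETS3 = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


class Param:
    """A trainable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Module):
    """3x3x3 convolution, stride 1, zero padding 1 (shape preserving).

    Implemented as 27 shifted channel-matmuls, which keeps peak memory at one
    padded copy of the input instead of a full im2col buffer.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 27
        scale = np.sqrt(2.0 / fan_in)  # He init for (leaky) ReLU nets
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, 3, 3, 3)))
        self.b = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ci, d, h, w = x.shape
        co = self.w.value.shape[0]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp = xp
        out = np.zeros((co, d * h * w), dtype=xp.dtype)
        for a, b, c in _OFFSETS3:
            sl = xp[:, a : a + d, b : b + h, c : c + w].reshape(ci, -1)
            out += self.w.value[:, :, a, b, c] @ sl
        out += self.b.value[:, None]
        return out.reshape(co, d, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "backward before forward"
        co, d, h, w = gy.shape
        ci = xp.shape[0]
        gy2 = gy.reshape(co, -1)
        gxp = np.zeros_like(xp)
        for a, b, c in _OFFSETS3:
            sl = xp[:, a : a + d, b : b + h, c : c + w].reshape(ci, -1)
            self.w.grad[:, :, a, b, c] += gy2 @ sl.T
            gxp[:, a : a + d, b : b + h, c : c + w] += (
                self.w.value[:, :, a, b, c].T @ gy2
            ).reshape(ci, d, h, w)
        self.b.grad += gy2.sum(axis=1)
        self._xp = None
        return gxp[:, 1:-1, 1:-1, 1:-1]


class Conv1x1(Module):
    """Pointwise (1x1x1) convolution; used for the output head."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / c_in)
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in)))
        self.b = Param(np.zeros(c_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        ci, d, h, w = x.shape
        out = self.w.value @ x.reshape(ci, -1) + self.b.value[:, None]
        return out.reshape(-1, d, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        co, d, h, w = gy.shape
        gy2 = gy.reshape(co, -1)
        x2 = x.reshape(x.shape[0], -1)
        self.w.grad += gy2 @ x2.T
        self.b.grad += gy2.sum(axis=1)
        self._x = None
        return (self.w.value.T @ gy2).reshape(x.shape)


class ConvTranspose3d2x(Module):
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    Kernel and stride coincide, so output blocks do not overlap and the
    operation is a channel mix followed by a reshape.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 8))
        self.w = Param(rng.normal(0.0, scale, size=(c_in, c_out, 2, 2, 2)))
        self.b = Param(np.zeros(c_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        ci, d, h, w = x.shape
        co = self.w.value.shape[1]
        out6 = np.einsum("ioabc,idhw->odahbwc", self.w.value, x, optimize=True)
        out = out6.reshape(co, 2 * d, 2 * h, 2 * w)
        return out + self.b.value[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        ci, d, h, w = x.shape
        co = gy.shape[0]
        gy6 = gy.reshape(co, d, 2, h, 2, w, 2)
        self.w.grad += np.einsum("odahbwc,idhw->ioabc", gy6, x, optimize=True)
        self.b.grad += gy.sum(axis=(1, 2, 3))
        gx = np.einsum("odahbwc,ioabc->idhw", gy6, self.w.value, optimize=True)
        self._x = None
        return gx


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        mask = self._mask
        assert mask is not None
        self._mask = None
        return np.where(mask, gy, self.slope * gy)


class InstanceNorm(Module):
    """Per-channel normalization over spatial dims with affine parameters.

    Optional: its statistics depend on the whole input, so networks using it
    lose exact equivalence between tiled and untiled inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        x2 = x.reshape(c, -1)
        mu = x2.mean(axis=1, keepdims=True)
        var = x2.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x2 - mu) * inv
        self._cache = (xhat, inv, x.shape)
        out = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        return out.reshape(x.shape).astype(x.dtype, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache  # type: ignore[misc]
        c = gy.shape[0]
        gy2 = gy.reshape(c, -1)
        n = gy2.shape[1]
        self.gamma.grad += (gy2 * xhat).sum(axis=1)
        self.beta.grad += gy2.sum(axis=1)
        gxhat = gy2 * self.gamma.value[:, None]
        gx = (inv / n) * (
            n * gxhat - gxhat.sum(axis=1, keepdims=True) - xhat * (gxhat * xhat).sum(axis=1, keepdims=True)
        )
        self._cache = None
        return gx.reshape(shape)


class MaxPool2(Module):
    """2x2x2 max pooling (all spatial dims must be even)."""

    def __init__(self):
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache  # type: ignore[misc]
        c, d, h, w = shape
        gxr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
        np.put_along_axis(gxr, idx[..., None], gy[..., None], axis=-1)
        gx = (
            gxr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(shape)
        )
        self._cache = None
        return gx


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
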