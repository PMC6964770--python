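"""Minimal NumPy layer framework for 3D convolutional networks.

Tensors are ``(N, C, D, H, W)`` float32 arrays. Every layer implements
``forward(x, train)`` and ``backward(grad_out)`` and exposes its trainable
parameters as :class:`Param` objects so an optimizer can walk them
generically. Backward passes are exact gradients (verified against
finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Param:
    """A trainable array with its accumulated gradient."""

    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    regularized: bool = False  # True for conv/FC kernels (L1/L2 penalties)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """Zero-padded "same" 3D convolution (cross-correlation) with bias.

    Weights are He-normal initialized from the provided generator. A
    ``padding="valid"`` mode shrinks the output by (k-1) per axis.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None, bias: bool = True,
                 padding: str = "same", name: str = "conv"):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel edge must be odd, got {kernel}")
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel, kernel))
        self.W = Param(f"{name}.W", w, regularized=True)
        self.b = Param(f"{name}.b", np.zeros(out_ch)) if bias else None
        self.kernel = kernel
        self.padding = padding
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "valid":
            return x
        h = self.kernel // 2
        return np.pad(x, ((0, 0), (0, 0), (h, h), (h, h), (h, h)))

    @staticmethod
    def _cmajor(v: np.ndarray) -> np.ndarray:
        """Copy a (N, C, D, H, W) view to a contiguous (C, N*D*H*W) matrix."""
        c = v.shape[1]
        return np.ascontiguousarray(np.moveaxis(v, 1, 0)).reshape(c, -1)

    def _wflat(self) -> np.ndarray:
        """Kernel as an (out_ch, k^3 * in_ch) matrix, offset-major rows."""
        return np.ascontiguousarray(
            np.moveaxis(self.W.value, 1, -1).reshape(self.out_ch, -1))

    def _im2col(self, xp: np.ndarray, dd: int, hh: int, ww: int) -> np.ndarray:
        """Offset-major im2col matrix (k^3 * in_ch, N * D * H * W)."""
        k, c = self.kernel, self.in_ch
        m = xp.shape[0] * dd * hh * ww
        xcol = np.empty((k**3 * c, m), dtype=np.float32)
        off = 0
        for a in range(k):
            for b in range(k):
                for g in range(k):
                    xcol[off * c:(off + 1) * c] = self._cmajor(
                        xp[:, :, a:a + dd, b:b + hh, g:g + ww])
                    off += 1
        return xcol

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        n = x.shape[0]
        k = self.kernel
        if k == 1:
            xcol = self._cmajor(x)
            dd, hh, ww = x.shape[2:]
        else:
            xp = self._pad(x)
            dd = xp.shape[2] - k + 1
            hh = xp.shape[3] - k + 1
            ww = xp.shape[4] - k + 1
            xcol = self._im2col(xp, dd, hh, ww)
        self._cache = (xcol, n, dd, hh, ww) if train else None
        ymat = self._wflat() @ xcol
        y = np.moveaxis(ymat.reshape(self.out_ch, n, dd, hh, ww), 0, 1)
        if self.b is not None:
            y = y + self.b.value[None, :, None, None, None]
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a training forward pass")
        xcol, n, dd, hh, ww = self._cache
        k, c = self.kernel, self.in_ch
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        gmat = self._cmajor(grad)  # (out_ch, N*D*H*W)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        gwf = gmat @ xcol.T  # (out_ch, k^3 * in_ch)
        self.W.grad += np.moveaxis(gwf.reshape(self.out_ch, k, k, k, c), -1, 1)
        gxcol = self._wflat().T @ gmat  # (k^3 * in_ch, N*D*H*W)
        if k == 1:
            gx = np.moveaxis(gxcol.reshape(c, n, dd, hh, ww), 0, 1)
            return np.ascontiguousarray(gx)
        if self.padding == "same":
            h = k // 2
            pd, ph, pw = dd + 2 * h, hh + 2 * h, ww + 2 * h
        else:
            pd, ph, pw = dd + k - 1, hh + k - 1, ww + k - 1
        gxp = np.zeros((n, c, pd, ph, pw), dtype=np.float32)
        off = 0
        for a in range(k):
            for b in range(k):
                for g in range(k):
                    t = gxcol[off * c:(off + 1) * c].reshape(c, n, dd, hh, ww)
                    gxp[:, :, a:a + dd, b:b + hh, g:g + ww] += np.moveaxis(t, 0, 1)
                    off += 1
        if self.padding == "same":
            h = k // 2
            gx = gxp[:, :, h:pd - h, h:ph - h, h:pw - h]
        else:
            gx = gxp
        return np.ascontiguousarray(gx, dtype=np.float32)


class BatchNorm3D(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return (self.gamma.value[None, :, None, None, None] * xhat
                + self.beta.value[None, :, None, None, None]).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        axes = (0, 2, 3, 4)
        m = np.prod([shape[i] for i in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        dxhat = grad * g
        # standard batchnorm backward through batch statistics
        gx = (inv[None, :, None, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )
        return gx.astype(np.float32)


class PReLU(Layer):
    """Channel-wise parametric ReLU, slope initialized to 0.25."""

    def __init__(self, channels: int, init: float = 0.25, name: str = "prelu"):
        self.a = Param(f"{name}.a", np.full(channels, init))
        self._x = None

    def params(self) -> list[Param]:
        return [self.a]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        a = self.a.value[None, :, None, None, None]
        return np.where(x > 0, x, a * x).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        neg = x <= 0
        self.a.grad += (grad * np.where(neg, x, 0.0)).sum(axis=(0, 2, 3, 4))
        a = self.a.value[None, :, None, None, None]
        return (grad * np.where(neg, a, 1.0)).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return (x * self._mask).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(np.float32)


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax along the class axis."""
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
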