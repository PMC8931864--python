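"""Minimal CNN building blocks on numpy arrays (NCHW), with explicit backprop.

Every layer exposes ``forward(x, training)`` and ``backward(grad_out)``;
trainable tensors live in ``layer.params`` (name -> array) with matching
gradients in ``layer.grads`` after a backward pass.  Convolutions are
evaluated as a single GEMM over im2col patches (stride 1, "same" zero
padding, odd kernel), which is where essentially all the arithmetic happens.
Caches required by backward are only stored when ``training=True``, so
inference on large frames stays memory-light.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base: parameter/gradient registry."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trainable state (BN running stats)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches under same zero padding."""
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    n, c, _, _ = x.shape
    win = sliding_window_view(x, (k, k), axis=(2, 3))      # (N, C, H, W, k, k)
    h, w = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    """Stride-1 same-padding convolution, odd square kernel (or 1x1)."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.params["kernel"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        if bias:
            self.params["bias"] = np.zeros(c_out)
        self._cache = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        w2 = self.params["kernel"].reshape(self.c_out, -1)
        y = cols @ w2.T
        if "bias" in self.params:
            y += self.params["bias"]
        y = y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape) if training else None
        return np.ascontiguousarray(y)

    def backward(self, grad):
        cols, xshape = self._cache
        n, c, h, w = xshape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads["kernel"] = (g.T @ cols).reshape(self.params["kernel"].shape)
        if "bias" in self.params:
            self.grads["bias"] = g.sum(axis=0)
        # input gradient: same-padding convolution of grad with the flipped,
        # transposed kernel (exact adjoint for stride-1 odd-k same padding)
        w_flip = self.params["kernel"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gcols = _im2col(grad, self.k)
        gx = gcols @ w_flip.reshape(self.c_in, -1).T
        gx = gx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        self._cache = None
        return np.ascontiguousarray(gx)


class BatchNorm2d(Layer):
    def __init__(self, name: str, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__(name)
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["bn_gamma"] = np.ones(c)
        self.params["bn_beta"] = np.zeros(c)
        self.buffers["bn_mean"] = np.zeros(c)
        self.buffers["bn_var"] = np.ones(c)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["bn_mean"] = (1 - m) * self.buffers["bn_mean"] + m * mean
            self.buffers["bn_var"] = (1 - m) * self.buffers["bn_var"] + m * var
        else:
            mean, var = self.buffers["bn_mean"], self.buffers["bn_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        y = self.params["bn_gamma"][:, None, None] * xhat + self.params["bn_beta"][:, None, None]
        self._cache = (xhat, invstd) if training else None
        return y

    def backward(self, grad):
        xhat, invstd = self._cache
        g = self.params["bn_gamma"]
        self.grads["bn_gamma"] = (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["bn_beta"] = grad.sum(axis=(0, 2, 3))
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        gxhat = grad * g[:, None, None]
        gx = (invstd[:, None, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 2, 3))[:, None, None]
            - xhat * (gxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        )
        self._cache = None
        return gx


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        super().__init__(name)
        self._mask = None

    def forward(self, x, training=False):
        y = np.maximum(x, 0.0)
        self._mask = x > 0 if training else None
        return y

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even input sides required)."""

    def __init__(self, name: str = "pool"):
        super().__init__(name)
        self._cache = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial sides")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape) if training else None
        return y

    def backward(self, grad):
        idx, xshape = self._cache
        n, c, h, w = xshape
        gb = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gb, idx[..., None], grad[..., None], axis=-1)
        gx = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(xshape)
        self._cache = None
        return gx


class ConvTranspose2(Layer):
    """2x2 stride-2 transposed convolution (learned x2 upsampling)."""

    def __init__(self, name: str, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        super().__init__(name)
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        self.params["kernel"] = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, 2, 2))
        self.params["bias"] = np.zeros(c_out)
        self._x = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        y = np.einsum("ncij,cdab->ndiajb", x, self.params["kernel"], optimize=True)
        y = y.reshape(n, self.c_out, 2 * h, 2 * w) + self.params["bias"][:, None, None]
        self._x = x if training else None
        return np.ascontiguousarray(y)

    def backward(self, grad):
        x = self._x
        n, d, H, W = grad.shape
        gb = grad.reshape(n, d, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)  # n,d,i,j,a,b
        self.grads["kernel"] = np.einsum("ncij,ndijab->cdab", x, gb, optimize=True)
        self.grads["bias"] = grad.sum(axis=(0, 2, 3))
        gx = np.einsum("ndijab,cdab->ncij", gb, self.params["kernel"], optimize=True)
        self._x = None
        return np.ascontiguousarray(gx)


class Dropout(Layer):
    """Inverted dropout; randomness supplied by the caller's generator."""

    def __init__(self, name: str, p: float):
        super().__init__(name)
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng: np.random.Generator | None = None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng(0)
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g
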