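"""Minimal convolutional network engine used by the pose model.

A compact, deterministic forward/backward engine over numpy arrays in
NCHW layout: strided convolution, transposed convolution, ReLU, and the
masked mean-squared-error loss used for heatmap regression, plus SGD and
Adam optimizers.  All layers expose ``params``/``grads`` dictionaries of
named tensors so a whole model can be flattened into a
:class:`~fedgh.params.ParamVector` and restored bit-exactly.

Computation is float32 internally (parameters are exchanged with the
federation layer as float64 flat vectors); backward passes are exact
gradients of the forward passes and are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "im2col", "col2im",
    "Conv2d", "ConvTranspose2d", "ReLU", "Sequential",
    "masked_mse", "SGD", "Adam",
]


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold (N,C,H,W) into (N, C·k·k, OH·OW) patch columns."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow)


def col2im(cols: np.ndarray, out_hw: tuple[int, int], k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back onto an image."""
    n, ckk, s = cols.shape
    oh, ow = out_hw
    c = ckk // (k * k)
    ih = (oh + 2 * pad - k) // stride + 1
    iw = (ow + 2 * pad - k) // stride + 1
    assert ih * iw == s, "column count inconsistent with target geometry"
    cols = cols.reshape(n, c, k, k, ih, iw)
    xp = np.zeros((n, c, oh + 2 * pad, ow + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ih : stride, j : j + stride * iw : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + oh, pad : pad + ow]


class Layer:
    """Base: stateless unless it declares ``params``/``grads``."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Strided 2-D convolution, weight (cout, cin, k, k)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        # He-style init: std = sqrt(2 / fan_in)
        std = np.sqrt(2.0 / (cin * k * k))
        self.params["w"] = rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        n, c, h, w = x.shape
        oh = (h + 2 * self.pad - self.k) // self.stride + 1
        ow = (w + 2 * self.pad - self.k) // self.stride + 1
        self._cols = im2col(x, self.k, self.stride, self.pad)
        wr = self.params["w"].reshape(self.cout, -1)
        out = np.einsum("oc,ncs->nos", wr, self._cols, optimize=True)
        out += self.params["b"][None, :, None]
        return out.reshape(n, self.cout, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        dflat = dout.reshape(n, self.cout, -1)
        wr = self.params["w"].reshape(self.cout, -1)
        self.grads["w"] = np.einsum("nos,ncs->oc", dflat, self._cols, optimize=True) \
            .reshape(self.params["w"].shape)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("oc,nos->ncs", wr, dflat, optimize=True)
        return col2im(dcols, self._x_shape[2:], self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed convolution (upsampling head), weight (cin, cout, k, k).

    Output size is (H−1)·stride − 2·pad + k per spatial dimension.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 2, pad: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.params["w"] = rng.normal(0.0, std, (cin, cout, k, k)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        f = lambda v: (v - 1) * self.stride - 2 * self.pad + self.k
        return f(h), f(w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        oh, ow = self.out_hw(h, w)
        wr = self.params["w"].reshape(self.cin, -1)  # (cin, cout·k·k)
        cols = np.einsum("ck,ncs->nks", wr, x.reshape(n, c, h * w), optimize=True)
        out = col2im(cols, (oh, ow), self.k, self.stride, self.pad)
        out += self.params["b"][None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = self._x.shape
        dcols = im2col(dout, self.k, self.stride, self.pad)  # (N, cout·k·k, h·w)
        xr = self._x.reshape(n, self.cin, h * w)
        self.grads["w"] = np.einsum("ncs,nks->ck", xr, dcols, optimize=True) \
            .reshape(self.params["w"].shape)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        wr = self.params["w"].reshape(self.cin, -1)
        dx = np.einsum("ck,nks->ncs", wr, dcols, optimize=True)
        return dx.reshape(self._x.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sequential(Layer):
    """Layer chain with namespaced parameter access ("<i>.<layername>.w")."""

    def __init__(self, layers: Sequence[tuple[str, Layer]]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for _, layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for pname, val in layer.params.items():
                out[f"{name}.{pname}"] = val
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for pname, val in layer.grads.items():
                out[f"{name}.{pname}"] = val
        return out

    def set_named_params(self, values: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for pname in layer.params:
                key = f"{name}.{pname}"
                if key in values:
                    layer.params[pname] = np.asarray(values[key], dtype=np.float32) \
                        .reshape(layer.params[pname].shape)


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over visible heatmap channels.

    ``mask`` is (N, K) with 1 for visible joints; invisible channels
    contribute neither loss nor gradient.  Returns (loss, dL/dpred).
    """
    m = mask[:, :, None, None].astype(pred.dtype)
    diff = (pred - target) * m
    denom = max(float(m.sum()) * pred.shape[2] * pred.shape[3], 1.0)
    loss = float((diff ** 2).sum()) / denom
    dpred = (2.0 / denom) * diff
    return loss, dpred


class SGD:
    def __init__(self, lr: float = 1e-2, momentum: float = 0.0) -> None:
        self.lr, self.momentum = lr, momentum
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, p in params.items():
            g = grads[k].astype(p.dtype)
            if self.momentum:
                v = self._v.setdefault(k, np.zeros_like(p))
                v *= self.momentum
                v -= self.lr * g
                p += v
            else:
                p -= self.lr * g


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for k, p in params.items():
            g = grads[k].astype(np.float32)
            m = self._m.setdefault(k, np.zeros_like(p))
            v = self._v.setdefault(k, np.zeros_like(p))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
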