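"""Minimal NumPy neural-network layers with manual backprop.

Shared by the convolutional VAE (:mod:`chromastate.representation`) and the
MLP classifiers (:mod:`chromastate.classify`). Everything is seeded through
an explicit ``numpy.random.Generator``, runs in float32, and is fully
deterministic on a single worker.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "LeakyReLU",
    "Dropout",
    "Adam",
    "Sequential",
    "softmax",
    "weighted_cross_entropy",
]

DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


# ---------------------------------------------------------------------------
# im2col / col2im


def im2col(x: np.ndarray, k: int, s: int, p: int):
    """Unfold ``x`` (N, C, H, W) into columns (N, C*k*k, Ho*Wo)."""
    n, c, h, w = x.shape
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    return cols.reshape(n, c * k * k, ho * wo), (ho, wo)


def col2im(cols: np.ndarray, x_shape, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back to (N, C, H, W)."""
    n, c, h, w = x_shape
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + s * ho : s, j : j + s * wo : s] += cols6[:, :, i, j]
    return xp[:, :, p : p + h, p : p + w] if p else xp


# ---------------------------------------------------------------------------
# Layers


class Layer:
    """Base layer: ``params()`` yields (value, grad) pairs by name."""

    def params(self):
        return {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": (self.W, self.gW), "b": (self.b, self.gb)}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gy):
        self.gW += self._x.T @ gy
        self.gb += gy.sum(axis=0)
        return gy @ self.W.T


class Conv2d(Layer):
    """Strided convolution via im2col; kernel 4, stride 2, pad 1 halves H/W."""

    def __init__(self, c_in, c_out, rng, k=4, s=2, p=1):
        self.k, self.s, self.p = k, s, p
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, (c_out, c_in * k * k), c_in * k * k)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": (self.W, self.gW), "b": (self.b, self.gb)}

    def forward(self, x, train=False):
        self._x_shape = x.shape
        cols, (ho, wo) = im2col(x, self.k, self.s, self.p)
        self._cols = cols
        out = np.einsum("oc,ncl->nol", self.W, cols, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, gy):
        n = gy.shape[0]
        gyf = gy.reshape(n, self.c_out, -1)
        self.gW += np.einsum("nol,ncl->oc", gyf, self._cols, optimize=True)
        self.gb += gyf.sum(axis=(0, 2))
        gcols = np.einsum("oc,nol->ncl", self.W, gyf, optimize=True)
        return col2im(gcols, self._x_shape, self.k, self.s, self.p)


class ConvTranspose2d(Layer):
    """Transposed convolution (adjoint of Conv2d); k=4, s=2, p=1 doubles H/W."""

    def __init__(self, c_in, c_out, rng, k=4, s=2, p=1):
        self.k, self.s, self.p = k, s, p
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, (c_in, c_out * k * k), c_in * k * k)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": (self.W, self.gW), "b": (self.b, self.gb)}

    def _out_hw(self, h, w):
        return (h - 1) * self.s - 2 * self.p + self.k, (w - 1) * self.s - 2 * self.p + self.k

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        self._xf = x.reshape(n, c, h * w)
        ho, wo = self._out_hw(h, w)
        cols = np.einsum("ck,ncl->nkl", self.W, self._xf, optimize=True)
        out = col2im(cols, (n, self.c_out, ho, wo), self.k, self.s, self.p)
        out += self.b[None, :, None, None]
        self._in_hw = (h, w)
        return out

    def backward(self, gy):
        n = gy.shape[0]
        gcols, _ = im2col(gy, self.k, self.s, self.p)
        self.gW += np.einsum("ncl,nkl->ck", self._xf, gcols, optimize=True)
        self.gb += gy.sum(axis=(0, 2, 3))
        gx = np.einsum("ck,nkl->ncl", self.W, gcols, optimize=True)
        h, w = self._in_hw
        return gx.reshape(n, self.c_in, h, w)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Needs an rng per forward run."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, pg in layer.params().items():
                out[f"{i}.{name}"] = pg
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


# ---------------------------------------------------------------------------
# Loss / optimizer


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits, y, class_weights):
    """Mean weighted CE and its gradient w.r.t. logits.

    ``class_weights[c]`` multiplies the loss of samples of class ``c``
    (inverse-class-frequency weighting upstream). Matches the usual
    weighted-softmax-CE convention of normalizing by the summed weights.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = class_weights[y]
    wsum = w.sum()
    ll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float((w * ll).sum() / wsum)
    g = p
    g[np.arange(n), y] -= 1.0
    g *= (w / wsum)[:, None]
    return loss, g.astype(DTYPE)


class Adam:
    """Adam with optional decoupled weight decay (AdamW-style)."""

    def __init__(self, model: Layer, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.state = {
            name: (np.zeros_like(p), np.zeros_like(p))
            for name, (p, _) in model.params().items()
        }

    def zero_grad(self):
        for _, (_, g) in self.model.params().items():
            g[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for name, (p, g) in self.model.params().items():
            m, v = self.state[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay and p.ndim > 1:  # decay weights, not biases
                p -= self.lr * self.weight_decay * p


def get_weights(model: Layer) -> dict:
    return {name: p.copy() for name, (p, _) in model.params().items()}


def set_weights(model: Layer, weights: dict) -> None:
    for name, (p, _) in model.params().items():
        p[...] = weights[name]
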