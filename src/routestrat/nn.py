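"""Minimal dense-network building blocks with explicit backpropagation.

Everything is plain numpy: parameters live in a flat ``dict[str, ndarray]``
so a whole model (embedding FFNN + tree-LSTM cell + scorer) shares one
parameter store, one gradient store and one optimizer.  Hidden layers are
rectified linear, outputs linear.  The first layer of the reaction
embedding network accepts a scipy CSR matrix because fingerprint inputs
are sparse.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import expit as sigmoid

DTYPE = np.float64


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


def accumulate(grads: dict, key: str, value: np.ndarray) -> None:
    """In-place gradient accumulation (avoids re-allocating large arrays)."""
    if key in grads:
        grads[key] += value
    else:
        grads[key] = value


class MLP:
    """Feed-forward net over a shared parameter dict, keys ``{prefix}.W{i}``.

    ``sizes = (n_in, h1, ..., n_out)``; ReLU after every layer except the
    last.  ``forward`` returns the output and a cache consumed by
    ``backward``, which accumulates into ``grads`` and returns the input
    gradient (dense even for sparse input).
    """

    def __init__(self, prefix: str, sizes: tuple[int, ...]):
        self.prefix = prefix
        self.sizes = tuple(sizes)

    def init(self, params: dict, rng: np.random.Generator) -> None:
        for i, (a, b) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            params[f"{self.prefix}.W{i}"] = glorot(rng, a, b)
            params[f"{self.prefix}.b{i}"] = np.zeros(b, dtype=DTYPE)

    def forward(self, params: dict, x) -> tuple[np.ndarray, list]:
        cache = [x]
        h = x
        n_layers = len(self.sizes) - 1
        for i in range(n_layers):
            z = h @ params[f"{self.prefix}.W{i}"] + params[f"{self.prefix}.b{i}"]
            if i < n_layers - 1:
                z = np.maximum(z, 0.0)
            cache.append(z)
            h = z
        return h, cache

    def backward(self, params: dict, grads: dict, cache: list, dout: np.ndarray):
        n_layers = len(self.sizes) - 1
        d = dout
        for i in reversed(range(n_layers)):
            h_in, h_out = cache[i], cache[i + 1]
            if i < n_layers - 1:
                d = d * (h_out > 0)
            wkey, bkey = f"{self.prefix}.W{i}", f"{self.prefix}.b{i}"
            if sp.issparse(h_in):
                dW = np.asarray(h_in.T @ d)
            else:
                h2 = np.atleast_2d(h_in)
                d2 = np.atleast_2d(d)
                dW = h2.T @ d2
            accumulate(grads, wkey, dW)
            accumulate(grads, bkey, np.atleast_2d(d).sum(axis=0))
            if i > 0:
                d = d @ params[wkey].T
        if sp.issparse(cache[0]):
            return None  # input gradient of the sparse layer is never needed
        return d @ params[f"{self.prefix}.W0"].T


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key in sorted(grads):
            g = grads[key]
            self.m[key] = b1 * self.m.get(key, 0.0) + (1 - b1) * g
            self.v[key] = b2 * self.v.get(key, 0.0) + (1 - b2) * (g * g)
        for key in sorted(grads):
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - np.max(x)
    e = np.exp(z)
    return e / e.sum()
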