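"""Minimal seeded multilayer perceptron with manual backprop and Adam.

Both neural components of the package — the 9-output Q-network and the
multi-head transition model — are small fixed-architecture feed-forward nets
(ReLU hidden layers, linear outputs, optional inverted dropout).  This module
implements exactly that, deterministically given a seed, with the per-sample
update path the on-policy learner needs.

Loss-specific gradients are computed by callers and passed in as ``dout``
(gradient of the loss w.r.t. the linear output), which keeps this module a pure
function approximator.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ArgumentError


class MLP:
    """Feed-forward net: linear layers, ReLU hidden activations, linear output.

    Parameters
    ----------
    layer_sizes:
        ``(input, hidden..., output)`` widths.
    dropout:
        Inverted-dropout rate applied to hidden activations during training
        passes (``train=True``); must be in [0, 1).
    seed:
        Seeds He-style weight initialization and the dropout stream.
    """

    def __init__(self, layer_sizes: tuple[int, ...], dropout: float = 0.0, seed: int = 0):
        if len(layer_sizes) < 2:
            raise ArgumentError("need at least input and output layer sizes")
        if not 0.0 <= dropout < 1.0:
            raise ArgumentError("dropout must be in [0, 1)")
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.dropout = float(dropout)
        self._rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(self._rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        # Adam state
        self._t = 0
        self._m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._v = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]

    # -- inference ---------------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False):
        """Return ``(output, cache)``; cache feeds :meth:`backward`.

        ``X`` may be a single feature vector or an ``(n, d)`` batch.
        """
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        acts = [X]
        drops: list[np.ndarray | None] = []
        h = X
        n_layers = len(self.W)
        for i in range(n_layers):
            z = h @ self.W[i] + self.b[i]
            if i < n_layers - 1:
                h = np.maximum(z, 0.0)
                if train and self.dropout > 0.0:
                    keep = 1.0 - self.dropout
                    mask = (self._rng.random(h.shape) < keep) / keep
                    h = h * mask
                    drops.append(mask)
                else:
                    drops.append(None)
                acts.append(h)
            else:
                h = z
        cache = (acts, drops)
        return (h[0] if single else h), cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False)[0]

    # -- training ----------------------------------------------------------
    def backward(self, cache, dout: np.ndarray):
        """Gradients of the loss given d(loss)/d(output) for the cached pass."""
        acts, drops = cache
        dout = np.atleast_2d(np.asarray(dout, dtype=float))
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if drops[i - 1] is not None:
                    delta = delta * drops[i - 1]
                delta = delta * (acts[i] > 0.0)
        return gW, gb

    def adam_step(self, grads, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        gW, gb = grads
        self._t += 1
        t = self._t
        params = self.W + self.b
        gall = list(gW) + list(gb)
        for p, g, m, v in zip(params, gall, self._m, self._v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * np.square(g)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- (de)serialization -------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.W] + [b.copy() for b in self.b]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n = len(self.W)
        if len(weights) != 2 * n:
            raise ArgumentError("weight list length mismatch")
        for i in range(n):
            if weights[i].shape != self.W[i].shape or weights[n + i].shape != self.b[i].shape:
                raise ArgumentError("weight shape mismatch")
            self.W[i] = weights[i].copy()
            self.b[i] = weights[n + i].copy()


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
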