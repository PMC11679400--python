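"""A minimal 1-D convolutional network engine with explicit backprop.

Layers operate on float64 arrays of shape (N, C, L) — batch, channels,
temporal length — or (N, F) once flattened.  Each layer implements
``forward(x, train)`` and ``backward(dy)``; parameters and their
gradients are exposed through ``params()`` as (value, grad) pairs that
the Adam optimizer updates in place.

The gradient-reversal layer is the piece that makes domain-adversarial
training work: it is the identity on the forward pass and multiplies the
gradient by -lambda on the backward pass, so minimising the domain
classifier's loss *maximises* domain confusion in the shared features.
Gradients of every layer are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return []


class Conv1d(Layer):
    """Same-padded 1-D convolution via im2col matmul."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        scale = np.sqrt(2.0 / (in_ch * kernel))  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch * kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        N, C, L = x.shape
        p = self.k // 2
        xp = np.zeros((N, C, L + 2 * p))
        xp[:, :, p : p + L] = x
        # (N, C, L, k) -> (N, L, C*k)
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        self._cols = cols.transpose(0, 2, 1, 3).reshape(N * L, C * self.k)
        self._shape = (N, C, L)
        y = self._cols @ self.W.T + self.b
        return y.reshape(N, L, self.out_ch).transpose(0, 2, 1)

    def backward(self, dy):
        N, C, L = self._shape
        dyc = dy.transpose(0, 2, 1).reshape(N * L, self.out_ch)
        self.dW[...] = dyc.T @ self._cols
        self.db[...] = dyc.sum(axis=0)
        dcols = (dyc @ self.W).reshape(N, L, C, self.k)
        p = self.k // 2
        dxp = np.zeros((N, C, L + 2 * p))
        for j in range(self.k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p : p + L]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm1d(Layer):
    """Domain-aware per-channel batch normalisation over (batch, length).

    Batch statistics are used during training and accumulated into
    running estimates; inference uses the frozen running stats.  When a
    per-row ``domains`` vector is set (via the ``domains`` attribute),
    statistics — both batch and running — are kept separately per
    domain while the affine parameters gamma/beta stay shared.  This is
    the domain-specific batch-norm construction from the adaptation
    literature: without it, one domain's activation scale swamps the
    shared batch statistics and cripples learning on the other.
    """

    def __init__(
        self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5, n_domains: int = 1
    ):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.dgamma = np.zeros(n_ch)
        self.dbeta = np.zeros(n_ch)
        self.run_mean = np.zeros((n_domains, n_ch))
        self.run_var = np.ones((n_domains, n_ch))
        self.momentum, self.eps = momentum, eps
        self.n_domains = n_domains
        self.domains: Optional[np.ndarray] = None  # per-row domain ids

    def _row_domains(self, n_rows: int) -> np.ndarray:
        if self.domains is None:
            return np.zeros(n_rows, dtype=int)
        return np.asarray(self.domains, dtype=int)

    def forward(self, x, train=False):
        dom = self._row_domains(x.shape[0])
        self._dom = dom
        self._train = train
        self._istd = np.empty((x.shape[0], x.shape[1]))
        self._xhat = np.empty_like(x)
        for g in np.unique(dom):
            rows = dom == g
            xg = x[rows]
            if train:
                mean = xg.mean(axis=(0, 2))
                var = xg.var(axis=(0, 2))
                self.run_mean[g] = (1 - self.momentum) * self.run_mean[g] + self.momentum * mean
                self.run_var[g] = (1 - self.momentum) * self.run_var[g] + self.momentum * var
            else:
                mean, var = self.run_mean[g], self.run_var[g]
            istd = 1.0 / np.sqrt(var + self.eps)
            self._istd[rows] = istd
            self._xhat[rows] = (xg - mean[None, :, None]) * istd[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dy):
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        dx = np.empty_like(dy)
        for g in np.unique(self._dom):
            rows = self._dom == g
            dyg = dy[rows]
            gg = self.gamma[None, :, None] * self._istd[rows][:, :, None]
            if not self._train:
                dx[rows] = dyg * gg
                continue
            xhat = self._xhat[rows]
            m = dyg.shape[0] * dyg.shape[2]
            dx[rows] = gg * (
                dyg
                - dyg.sum(axis=(0, 2))[None, :, None] / m
                - xhat * (dyg * xhat).sum(axis=(0, 2))[None, :, None] / m
            )
        return dx

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pool; an odd trailing element is dropped, so
    the output length is floor(L / size)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False):
        N, C, L = x.shape
        Lo = L // self.size
        xr = x[:, :, : Lo * self.size].reshape(N, C, Lo, self.size)
        self._arg = xr.argmax(axis=3)
        self._shape = (N, C, L)
        return xr.max(axis=3)

    def backward(self, dy):
        N, C, L = self._shape
        Lo = dy.shape[2]
        dxr = np.zeros((N, C, Lo, self.size))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros((N, C, L))
        dx[:, :, : Lo * self.size] = dxr.reshape(N, C, Lo * self.size)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GradientReversal(Layer):
    """Identity forward; gradient scaled by -lambda on the way back."""

    def __init__(self, lam: float = 1.0):
        if lam < 0:
            raise ValueError("gradient-reversal coefficient must be >= 0")
        self.lam = lam

    def forward(self, x, train=False):
        return x

    def backward(self, dy):
        return -self.lam * dy


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    sample_weight: Optional[np.ndarray] = None,
) -> Tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    wsum = w.sum()
    ll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    loss = float((w * ll).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
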