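"""Minimal numpy neural-network layers with explicit backpropagation.

Implements exactly the primitives the multistream risk network needs: 3x3
same-padding 2D convolution, batch normalisation, ReLU, sigmoid, inverted
dropout, dense layers, global average pooling, softmax cross-entropy and the
Adam optimiser.  Activations are float32 and channels-last (N, H, W, C); the
convolution is computed as nine accumulated matmuls over shifted views, which
avoids im2col copies and is the fastest layout for small channel counts on a
single CPU.

Each layer stores its forward cache on ``self`` and exposes ``params()``
returning ``[(weight, grad), ...]`` pairs of arrays updated in place by the
optimiser.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """kxk same-padding convolution, stride 1, channels-last."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        self.cin, self.cout, self.k = cin, cout, k
        self.W = _he_init(rng, (k, k, cin, cout), cin * k * k)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.empty((n, h, w, self.cout), dtype=np.float32)
        out[...] = self.b
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] @ self.W[i, j]
        self._xp = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = dout.shape
        k, p = self.k, self.k // 2
        xp = self._xp
        dmat = dout.reshape(-1, self.cout)
        # dx is the full correlation of dout with the flipped kernel; writing
        # into the contiguous output is cheaper than scattering into dxp
        dp = np.pad(dout, ((0, 0), (p, p), (p, p), (0, 0)))
        dx = np.zeros((n, h, w, self.cin), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx += dp[:, i : i + h, j : j + w, :] @ self.W[k - 1 - i, k - 1 - j].T
                xs = xp[:, i : i + h, j : j + w, :].reshape(-1, self.cin)
                self.dW[i, j] = xs.T @ dmat
        self.db[...] = dmat.sum(axis=0)
        return dx


class BatchNorm(Layer):
    """Batch normalisation over all axes except the trailing channel axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c = x.shape[-1]
        flat = x.reshape(-1, c)
        if train:
            n = flat.shape[0]
            s1 = np.einsum("nc->c", flat, optimize=True)
            s2 = np.einsum("nc,nc->c", flat, flat, optimize=True)
            mean = s1 / n
            var = np.maximum(s2 / n - mean * mean, 0.0)
            if getattr(self, "_recal", False):
                self._acc_mean += mean
                self._acc_var += var
                self._acc_n += 1
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        c = dout.shape[-1]
        m = dout.size / c
        dflat = dout.reshape(-1, c)
        xflat = xhat.reshape(-1, c)
        self.dgamma[...] = np.einsum("nc,nc->c", dflat, xflat, optimize=True)
        self.dbeta[...] = np.einsum("nc->c", dflat, optimize=True)
        # sum(dxhat) = gamma*dbeta and sum(dxhat*xhat) = gamma*dgamma
        dx = (inv * self.gamma) * (
            dout - self.dbeta / m - xhat * (self.dgamma / m)
        )
        return dx.astype(np.float32)

    def begin_recalibration(self) -> None:
        """Start accumulating exact batch statistics ("precise BN")."""
        self._recal = True
        self._acc_mean = np.zeros_like(self.running_mean, dtype=np.float64)
        self._acc_var = np.zeros_like(self.running_var, dtype=np.float64)
        self._acc_n = 0

    def finish_recalibration(self) -> None:
        self._recal = False
        if self._acc_n:
            self.running_mean = (self._acc_mean / self._acc_n).astype(np.float32)
            self.running_var = (self._acc_var / self._acc_n).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = out > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._mask).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._y * (1.0 - self._y)).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        self.W = _he_init(rng, (din, dout), din)
        self.b = np.zeros(dout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class GlobalAvgPool2d(Layer):
    """(N, H, W, C) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), self._shape
        ).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    ``weights`` are optional per-sample loss weights (e.g. inverse class
    frequencies); they are normalised to mean 1.
    """
    n = logits.shape[0]
    p = softmax(logits)
    ce = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.mean()
        ce = ce * w
        grad = grad * w[:, None]
    loss = float(ce.mean())
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # list of (weight, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (w, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            w -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
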