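"""Minimal feed-forward/convolutional network stack with manual backprop.

Implements exactly the pieces the architecture grid needs: dense layers,
ReLU, window-5 1-D convolutions with residual connections and skip
connections summed into a global max pool, and the AMSGrad variant of Adam
(with the usual bias-corrected step size and optional global-norm gradient
clipping). Everything operates on float32/float64 numpy arrays; no
third-party autodiff is involved.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Dense:
    """Affine layer ``Y = X W + b`` with fan-in scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: float = 1.0):
        std = gain * np.sqrt(1.0 / n_in)
        self.W = Param(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Conv1d:
    """Same-padded 1-D convolution over (batch, length, channels) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 gain: float = np.sqrt(2.0)):
        std = gain * np.sqrt(1.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, std, size=(kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        P = self.kernel // 2
        xp = np.pad(x, ((0, 0), (P, P), (0, 0)))
        self._xp = xp
        y = np.zeros((B, L, self.W.value.shape[2]), dtype=x.dtype)
        for k in range(self.kernel):
            y += xp[:, k:k + L] @ self.W.value[k]
        return y + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, _ = dy.shape
        P = self.kernel // 2
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel):
            self.W.grad[k] += np.tensordot(self._xp[:, k:k + L], dy, axes=([0, 1], [0, 1]))
            dxp[:, k:k + L] += dy @ self.W.value[k].T
        self.b.grad += dy.sum(axis=(0, 1))
        return dxp[:, P:P + L]


class ResidualConvNet:
    """Fully-convolutional classifier/regressor for variable-length input.

    ``n_blocks`` residual blocks (window-``kernel`` conv + ReLU, added back
    onto the block input); the outputs of every block, plus the stem, are
    summed (skip connections) into a global max pool whose pooled vector
    feeds the output head. Accepts one-hot input of any length >= 1.
    """

    def __init__(self, alphabet_size: int, n_blocks: int, n_outputs: int,
                 rng: np.random.Generator, filters: int = 100, kernel: int = 5):
        self.stem = Conv1d(alphabet_size, filters, kernel, rng)
        self.stem_act = ReLU()
        self.blocks = [Conv1d(filters, filters, kernel, rng) for _ in range(n_blocks)]
        self.acts = [ReLU() for _ in range(n_blocks)]
        self.head = Dense(filters, n_outputs, rng)
        self._cache = None

    def params(self):
        ps = self.stem.params() + [p for c in self.blocks for p in c.params()]
        return ps + self.head.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.stem_act.forward(self.stem.forward(x))
        skip = h.copy()
        hs = [h]
        for conv, act in zip(self.blocks, self.acts):
            h = h + act.forward(conv.forward(h))
            skip += h
            hs.append(h)
        arg = skip.argmax(axis=1)  # (B, C)
        pooled = np.take_along_axis(skip, arg[:, None, :], axis=1)[:, 0, :]
        self._cache = (hs, arg, x.shape)
        return self.head.forward(pooled)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        hs, arg, (B, L, _) = self._cache
        dpooled = self.head.backward(dy)
        dskip = np.zeros((B, L, dpooled.shape[1]), dtype=dpooled.dtype)
        np.put_along_axis(dskip, arg[:, None, :], dpooled[:, None, :], axis=1)
        # every block output (and the stem) received dskip through the skip sum
        dh = dskip.copy()
        for conv, act in zip(reversed(self.blocks), reversed(self.acts)):
            dh_prev = dh + conv.backward(act.backward(dh))
            dh = dh_prev + dskip
        return self.stem.backward(self.stem_act.backward(dh))


class AMSGrad:
    """AMSGrad Adam variant with bias-corrected step size.

    ``epsilon`` sits outside the square root, matching the common deep
    learning framework convention whose default (1e-7) the training recipe
    assumes. ``clip`` applies global-norm gradient clipping before the step.
    """

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, clip: float | None = None):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.clip = lr, beta1, beta2, eps, clip
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.vhat = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        if self.clip is not None:
            norm = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in self.params))
            if norm > self.clip:
                scale = self.clip / (norm + 1e-12)
                for p in self.params:
                    p.grad *= scale
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2 ** self.t) / (1.0 - self.b1 ** self.t)
        for p, m, v, vh in zip(self.params, self.m, self.v, self.vhat):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            np.maximum(vh, v, out=vh)
            p.value -= lr_t * m / (np.sqrt(vh) + self.eps)
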