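"""Minimal NumPy neural-network primitives for the beta-VAE.

Implements exactly what the model needs — strided 1-D convolutions,
transposed convolutions (zero-insertion upsampling followed by a stride-1
convolution), dense layers, ELU activations and Adam — with explicit
forward/backward passes.  All computation is float32; randomness flows
through a single ``numpy.random.Generator`` so training is bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    params: list
    grads: list

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv1d(Layer):
    """1-D convolution with stride ``s`` and padding chosen so that an
    input of length L maps to L // s (L divisible by s)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad_total: int | None = None):
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, kernel, stride
        if pad_total is None:
            pad_total = kernel - stride
        if pad_total < 0:
            raise ValueError("kernel must be >= stride")
        self.pad_l = pad_total // 2
        self.pad_r = pad_total - self.pad_l
        self.W = _he_init(rng, (c_out, c_in, kernel), c_in * kernel)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        L_out = (xp.shape[2] - self.k) // self.s + 1
        idx = np.arange(L_out)[:, None] * self.s + np.arange(self.k)[None, :]
        self._cols = xp[:, :, idx]  # (B, C, L_out, K)
        self._xp_len = xp.shape[2]
        y = np.einsum("bclk,fck->bfl", self._cols, self.W, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("bfl,bclk->fck", dy, self._cols, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        dcols = np.einsum("bfl,fck->bclk", dy, self.W, optimize=True)
        B, C = dcols.shape[:2]
        L_out = dy.shape[2]
        dxp = np.zeros((B, C, self._xp_len), dtype=DTYPE)
        for j in range(self.k):
            dxp[:, :, j:j + self.s * L_out:self.s] += dcols[:, :, :, j]
        return dxp[:, :, self.pad_l:self._xp_len - self.pad_r or None]


class ConvTranspose1d(Layer):
    """Transposed convolution doubling (or s-folding) the length: zero
    insertion at stride ``s`` followed by a stride-1 convolution padded so
    an input of length L maps to s * L."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, stride: int = 2):
        self.s = stride
        self.conv = Conv1d(rng, c_in, c_out, kernel, stride=1, pad_total=kernel - 1)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        xu = np.zeros((B, C, self.s * L), dtype=DTYPE)
        xu[:, :, ::self.s] = x
        return self.conv.forward(xu)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dxu = self.conv.backward(dy)
        return dxu[:, :, ::self.s]


class Dense(Layer):
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ELU(Layer):
    params: list = []
    grads: list = []

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.where(x > 0, x, np.expm1(x)).astype(DTYPE)
        self._pos = x > 0
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * np.where(self._pos, 1.0, self._y + 1.0).astype(DTYPE)


class Adam:
    """Adam optimiser over a flat list of (param, grad) pairs."""

    def __init__(self, params: list, grads: list, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
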