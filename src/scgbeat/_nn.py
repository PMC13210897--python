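"""Minimal NumPy layer library for 1D segmentation networks.

Implements exactly the pieces the encoder–decoder needs — same-padded 1D
convolution (im2col + BLAS matmul), batch normalisation, ReLU, stride-2 max
pooling, stride-2 transposed convolution, channel concatenation, softmax
cross-entropy with class weights, and Adam.  Everything runs on the CPU,
is deterministic for a fixed seed, and supports float32 (default) or
float64 (used by the numerical gradient checks).

Array convention: activations are ``(N, C, L)``.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "ConvTranspose1d",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


class Layer:
    """Base class: stateless unless it declares parameters."""

    def parameters(self) -> list[dict]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1D convolution, He-initialised."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size
        self.W = (
            rng.standard_normal((out_channels, fan_in)) * np.sqrt(2.0 / fan_in)
        ).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._pad_l = (kernel_size - 1) // 2
        self._pad_r = kernel_size - 1 - self._pad_l

    def parameters(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self._pad_l, self._pad_r)))
        sw = sliding_window_view(xp, self.k, axis=2)  # (N, C, L, K)
        return np.ascontiguousarray(sw.transpose(0, 2, 1, 3)).reshape(
            n, length, c * self.k
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        self._col = self._im2col(x)
        y = self._col @ self.W.T + self.b  # (N, L, Cout)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (N, L, Cout)
        self.dW[...] = np.einsum("nlo,nlk->ok", dyt, self._col, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2))
        dcol = (dyt @ self.W).reshape(n, length, c, self.k)
        dxp = np.zeros((n, c, length + self.k - 1), dtype=dy.dtype)
        for k in range(self.k):
            dxp[:, :, k : k + length] += dcol[:, :, :, k].transpose(0, 2, 1)
        self._col = None
        return dxp[:, :, self._pad_l : self._pad_l + length]


class BatchNorm1d(Layer):
    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def parameters(self) -> list[dict]:
        return [
            {"value": self.gamma, "grad": self.dgamma},
            {"value": self.beta, "grad": self.dbeta},
        ]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._xhat = (x - mean[None, :, None]) * self._inv_std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n_eff = dy.shape[0] * dy.shape[2]
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None] * self._inv_std[None, :, None]
        dx = g * (
            dy
            - self.dbeta[None, :, None] / n_eff
            - self._xhat * self.dgamma[None, :, None] / n_eff
        )
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1d(Layer):
    """Kernel-2, stride-2 max pooling (requires even length)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, length = x.shape
        if length % 2:
            raise ValueError(f"pooling requires even length; got {length}")
        r = x.reshape(n, c, length // 2, 2)
        self._take_second = r[:, :, :, 1] > r[:, :, :, 0]
        return np.where(self._take_second, r[:, :, :, 1], r[:, :, :, 0])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, half = dy.shape
        dx = np.zeros((n, c, half, 2), dtype=dy.dtype)
        dx[:, :, :, 0] = np.where(self._take_second, 0, dy)
        dx[:, :, :, 1] = np.where(self._take_second, dy, 0)
        self._take_second = None
        return dx.reshape(n, c, half * 2)


class ConvTranspose1d(Layer):
    """Kernel-2, stride-2 transposed convolution (exact 2x upsampling)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        fan_in = in_channels * 2
        self.W = (
            rng.standard_normal((2, out_channels, in_channels))
            * np.sqrt(2.0 / fan_in)
        ).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        n, c, length = x.shape
        y = np.empty((n, self.W.shape[1], 2 * length), dtype=x.dtype)
        for phase in range(2):
            y[:, :, phase::2] = np.einsum(
                "ncl,oc->nol", x, self.W[phase], optimize=True
            )
        return y + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros_like(self._x)
        for phase in range(2):
            dyp = dy[:, :, phase::2]
            self.dW[phase] = np.einsum(
                "nol,ncl->oc", dyp, self._x, optimize=True
            )
            dx += np.einsum("nol,oc->ncl", dyp, self.W[phase], optimize=True)
        self.db[...] = dy.sum(axis=(0, 2))
        self._x = None
        return dx


class Adam:
    """Adam optimiser over a flat list of parameter dicts."""

    def __init__(self, params: list[dict], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p["value"] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-sample class-weighted cross entropy.

    ``logits``: (N, classes, L); ``targets``: (N, L) integer labels.
    Returns the scalar loss (weighted mean of per-sample NLL) and the
    gradient with respect to the logits.
    """
    p = softmax(logits, axis=1)
    n, n_classes, length = logits.shape
    w = np.asarray(class_weights, dtype=logits.dtype)
    sample_w = w[targets]  # (N, L)
    total_w = sample_w.sum()
    idx_n, idx_l = np.indices(targets.shape)
    p_true = p[idx_n, targets, idx_l]
    loss = float((sample_w * -np.log(np.maximum(p_true, 1e-12))).sum() / total_w)

    grad = p.copy()
    grad[idx_n, targets, idx_l] -= 1.0
    grad *= (sample_w / total_w)[:, None, :]
    return loss, grad
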