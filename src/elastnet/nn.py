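"""Minimal NumPy neural-network engine for the 1-D convolutional regressors.

Implements exactly the pieces the elastance networks need — Conv1d
(stride/padding), ReLU, MaxPool1d, Flatten, Linear, mean-squared-error
loss and the Adam optimizer — with explicit forward/backward passes on
float64 arrays. Weight initialization follows the common fan-in uniform
scheme U(-1/sqrt(fan_in), 1/sqrt(fan_in)) for weights and biases, with a
dedicated seeded Generator so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "ReLU", "MaxPool1d", "Flatten", "Linear", "Sequential", "Adam", "mse_loss"]


class Layer:
    """Base layer: parameters in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _fanin_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Layer):
    """1-D convolution with zero padding, implemented via window gathering."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, padding: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        fan_in = in_channels * kernel
        self.W = _fanin_uniform(rng, (out_channels, in_channels, kernel), fan_in)
        self.b = _fanin_uniform(rng, (out_channels,), fan_in)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        K, S, P = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (P, P)))
        L_out = (L + 2 * P - K) // S + 1
        idx = (np.arange(L_out) * S)[:, None] + np.arange(K)[None, :]
        # im2col: (B, L_out, C*K) rows against (F, C*K) filters via BLAS
        cols = xp[:, :, idx].transpose(0, 2, 1, 3).reshape(B * L_out, C * K)
        self._cols = cols
        self._geom = (B, C, L, L_out)
        F = self.W.shape[0]
        out = cols @ self.W.reshape(F, C * K).T
        return out.reshape(B, L_out, F).transpose(0, 2, 1) + self.b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, L, L_out = self._geom
        K, S, P = self.kernel, self.stride, self.padding
        F = self.W.shape[0]
        g2 = gy.transpose(0, 2, 1).reshape(B * L_out, F)
        self.grads[0][...] = (g2.T @ self._cols).reshape(F, C, K)
        self.grads[1][...] = gy.sum(axis=(0, 2))
        gcols = (g2 @ self.W.reshape(F, C * K)).reshape(B, L_out, C, K).transpose(0, 2, 1, 3)
        gxp = np.zeros((B, C, L + 2 * P))
        # col2im: strided slice-adds, one per kernel tap
        for k in range(K):
            gxp[:, :, k : k + S * L_out : S] += gcols[:, :, :, k]
        return gxp[:, :, P : P + L]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool1d(Layer):
    """Max pooling without padding; ties resolve to the first maximum."""

    def __init__(self, kernel: int, stride: int) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        L_out = (L - self.kernel) // self.stride + 1
        idx = (np.arange(L_out) * self.stride)[:, None] + np.arange(self.kernel)[None, :]
        windows = x[:, :, idx]                        # (B, C, L_out, K)
        self._arg = windows.argmax(axis=3)
        self._idx = idx
        self._xshape = x.shape
        return windows.max(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, L = self._xshape
        L_out = gy.shape[2]
        gx = np.zeros((B, C, L))
        src = self._idx[np.arange(L_out)[None, None, :], self._arg]  # (B, C, L_out)
        bidx = np.arange(B)[:, None, None]
        cidx = np.arange(C)[None, :, None]
        np.add.at(gx, (bidx, cidx, src), gy)
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _fanin_uniform(rng, (out_features, in_features), in_features)
        self.b = _fanin_uniform(rng, (out_features,), in_features)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = gy.T @ self._x
        self.grads[1][...] = gy.sum(axis=0)
        return gy @ self.W


class Sequential:
    """Plain layer chain with explicit forward/backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size


class Adam:
    """Adam optimizer with the standard moment coefficients (0.9, 0.999)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.grads = grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
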