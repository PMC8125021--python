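"""Minimal NumPy neural-network layers with explicit backpropagation.

Activations are ``(N, T, V, C)`` float32 tensors — batch, time rows, joints,
channels.  Every layer caches what its backward pass needs on ``forward`` and
accumulates parameter gradients into ``grads`` on ``backward``.  The gradient
arithmetic is verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: parameter dict, gradient dict, forward/backward pair."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class LinearMap(Layer):
    """Per-position channel-mixing map: ``y = x @ W + b`` on the last axis.

    This is the "linear map" that restores the channel count after DAG
    expansion triples it at the start of each layer.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / c_in)
        self.params = {
            "W": (rng.standard_normal((c_in, c_out)) * std).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        self._x = x
        c_out = self.params["W"].shape[1]
        y = x.reshape(-1, x.shape[-1]) @ self.params["W"] + self.params["b"]
        return y.reshape(x.shape[:-1] + (c_out,))

    def backward(self, g):
        c_in = self.params["W"].shape[0]
        x2 = self._x.reshape(-1, c_in)
        g2 = g.reshape(-1, g.shape[-1])
        self.grads["W"] += x2.T @ g2
        self.grads["b"] += g2.sum(axis=0)
        return (g2 @ self.params["W"].T).reshape(self._x.shape)


class BatchNorm(Layer):
    """Per-channel batch normalization over the (batch, time, joint) axes."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(c, dtype=DTYPE),
            "beta": np.zeros(c, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            mom = self.momentum
            self.running_mean += mom * (mean - self.running_mean)
            self.running_var += mom * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        # fused affine y = x * scale + shift; xhat is rebuilt on demand in
        # backward (keeps the forward to a single pass over x)
        scale = (self.params["gamma"] / std).astype(x.dtype)
        shift = (self.params["beta"] - mean * scale).astype(x.dtype)
        self._cache = (x, mean.astype(x.dtype), std.astype(x.dtype), axes, train)
        return x * scale + shift

    def backward(self, g):
        x, mean, std, axes, train = self._cache
        xhat = (x - mean)
        xhat /= std
        g_dot_xhat = (g * xhat).sum(axis=axes)
        g_sum = g.sum(axis=axes)
        self.grads["gamma"] += g_dot_xhat
        self.grads["beta"] += g_sum
        scale = self.params["gamma"] / std
        if not train:
            return g * scale
        m = np.prod([x.shape[a] for a in axes])
        gx = g - g_sum / m
        xhat *= g_dot_xhat / m
        gx -= xhat
        gx *= scale
        return gx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class TemporalConv(Layer):
    """2D convolution with a ``(K, 1)`` kernel: temporal only, per joint,
    with full channel mixing.  Stride and padding act on the time axis."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 9,
        stride: int = 1,
        pad: int = 4,
    ):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        std = np.sqrt(2.0 / (c_in * kernel))
        self.params = {
            "W": (rng.standard_normal((kernel, c_in, c_out)) * std).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def out_length(self, t: int) -> int:
        return (t + 2 * self.pad - self.kernel) // self.stride + 1

    def _im2col(self, xp, t_out):
        # (n, t_out, v, c, k) patches of the padded input, one contiguous copy
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        return np.ascontiguousarray(win[:, :: self.stride])

    def forward(self, x, train=True):
        n, t, v, c = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0), (0, 0)))
        t_out = self.out_length(t)
        self._xp, self._t = xp, t
        col = self._im2col(xp, t_out)
        w2 = np.ascontiguousarray(
            self.params["W"].transpose(1, 0, 2)
        ).reshape(c * self.kernel, -1)  # (c*k, c_out) matching col's layout
        self._w2 = w2
        y = col.reshape(-1, c * self.kernel) @ w2 + self.params["b"]
        return y.reshape(n, t_out, v, -1)

    def backward(self, g):
        xp, t = self._xp, self._t
        n, t_out, v, c_out = g.shape
        c = xp.shape[-1]
        k = self.kernel
        g2 = g.reshape(-1, c_out)
        col = self._im2col(xp, t_out).reshape(-1, c * k)
        gw2 = col.T @ g2  # (c*k, c_out)
        self.grads["W"] += gw2.reshape(c, k, c_out).transpose(1, 0, 2)
        self.grads["b"] += g2.sum(axis=0)
        gcol = (g2 @ self._w2.T).reshape(n, t_out, v, c, k)
        gxp = np.zeros_like(xp)
        for kk in range(k):
            sl = slice(kk, kk + self.stride * t_out, self.stride)
            gxp[:, sl] += gcol[..., kk]
        return gxp[:, self.pad : self.pad + t]


class DagExpand(Layer):
    """Channel expansion ``[X, X S^T, X T^T]`` along the joint axis.

    ``S`` and ``T`` are the normalized DAG incidence matrices; with
    ``enabled=False`` the identity variant ``[X, X, X]`` is used instead
    (the no-DAG ablation), which triples channels without mixing joints.
    """

    def __init__(self, S: np.ndarray, T: np.ndarray, enabled: bool = True):
        super().__init__()
        self.S = S.astype(DTYPE)
        self.T = T.astype(DTYPE)
        self.enabled = enabled

    def _mix(self, x: np.ndarray, M: np.ndarray) -> np.ndarray:
        # y[n,t,j,c] = sum_v x[n,t,v,c] * M[j,v]
        return np.moveaxis(np.tensordot(x, M, axes=([2], [1])), 3, 2)

    def forward(self, x, train=True):
        if not self.enabled:
            return np.concatenate([x, x, x], axis=-1)
        return np.concatenate(
            [x, self._mix(x, self.S), self._mix(x, self.T)], axis=-1
        )

    def backward(self, g):
        c = g.shape[-1] // 3
        g0, g1, g2 = g[..., :c], g[..., c : 2 * c], g[..., 2 * c :]
        if not self.enabled:
            return g0 + g1 + g2
        # d/dx of y = x M^T (joint axis) is g M
        return (
            g0
            + np.moveaxis(np.tensordot(g1, self.S, axes=([2], [0])), 3, 2)
            + np.moveaxis(np.tensordot(g2, self.T, axes=([2], [0])), 3, 2)
        )


class GlobalAvgPool(Layer):
    """Average over the time and joint axes: ``(N, T, V, C) -> (N, C)``."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, t, v, c = self._shape
        return np.broadcast_to(g[:, None, None, :], self._shape) / (t * v)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / c_in)
        self.params = {
            "W": (rng.standard_normal((c_in, c_out)) * std).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] += self._x.T @ g
        self.grads["b"] += g.sum(axis=0)
        return g @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)
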