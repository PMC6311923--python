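"""1-D neural-network layers with explicit forward/backward passes.

All layers operate on float32 arrays shaped (batch, channels, length) for
convolutional stages and (batch, features) after the pyramid-pooling head.
Each layer caches what its backward pass needs during forward; backward
returns the gradient with respect to the layer input and accumulates
parameter gradients in ``.grads`` (aligned with ``.params``).

Convolutions use "same" padding via im2col + matmul so both directions run
on BLAS; the input gradient of a convolution is itself a convolution with
the channel-transposed, kernel-flipped weights.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ModelConfigError


class Layer:
    """Base layer: parameters, gradients, forward/backward."""

    def __init__(self) -> None:
        self.params: List[np.ndarray] = []
        self.grads: List[np.ndarray] = []
        self.param_names: List[str] = []
        self.trainable = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def children(self) -> Sequence["Layer"]:
        return ()

    def named_parameters(self, prefix: str = ""):
        for name, p in zip(self.param_names, self.params):
            yield f"{prefix}{name}", p
        for i, child in enumerate(self.children()):
            yield from child.named_parameters(f"{prefix}{i}.")

    def named_gradients(self, prefix: str = ""):
        for name, g in zip(self.param_names, self.grads):
            yield f"{prefix}{name}", g
        for i, child in enumerate(self.children()):
            yield from child.named_gradients(f"{prefix}{i}.")

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0
        for child in self.children():
            child.zero_grad()

    def buffers(self, prefix: str = ""):
        """Non-trainable state (e.g. batch-norm running statistics)."""
        for i, child in enumerate(self.children()):
            yield from child.buffers(f"{prefix}{i}.")

    def set_rng(self, rng: np.random.Generator) -> None:
        for child in self.children():
            child.set_rng(rng)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, L) -> (N*L, C*k) column matrix under same padding."""
    n, c, length = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)  # (N, C, L, k)
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * length, c * k)


class Conv1d(Layer):
    """Same-padding 1-D convolution with odd kernel size."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, gain: float = 2.0):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ModelConfigError("kernel size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        std = np.sqrt(gain / (in_channels * kernel_size))
        self.W = rng.normal(0.0, std, (out_channels, in_channels, kernel_size)
                            ).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.param_names = ["W", "b"]
        self._cols: Optional[np.ndarray] = None
        self._shape: Optional[Tuple[int, ...]] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ModelConfigError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        n, _, length = x.shape
        cols = _im2col(x, self.kernel_size)
        self._cols, self._shape = cols, x.shape
        wm = self.W.transpose(1, 2, 0).reshape(-1, self.out_channels)
        y = cols @ wm + self.b
        return y.reshape(n, length, self.out_channels).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, length = self._shape
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(
            n * length, self.out_channels)
        dwm = self._cols.T @ dyr  # (C*k, out)
        self.grads[0] += dwm.reshape(
            self.in_channels, self.kernel_size, self.out_channels
        ).transpose(2, 0, 1)
        self.grads[1] += dyr.sum(axis=0)
        self._cols = None
        # input gradient: convolve dy with transposed, flipped kernels
        wt = self.W[:, :, ::-1].transpose(1, 0, 2)  # (in, out, k)
        cols = _im2col(dy, self.kernel_size)
        dx = cols @ wt.transpose(1, 2, 0).reshape(-1, self.in_channels)
        return dx.reshape(n, length, self.in_channels).transpose(0, 2, 1)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GatedConv1d(Layer):
    """Gated convolution: linear_conv(x) * sigmoid(gate_conv(x)).

    Two independent kernel/bias sets (GLU-style gating); output length
    equals input length.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.linear = Conv1d(in_channels, out_channels, kernel_size, rng)
        self.gate = Conv1d(in_channels, out_channels, kernel_size, rng)
        self.out_channels = out_channels
        self._a: Optional[np.ndarray] = None
        self._s: Optional[np.ndarray] = None

    def children(self):
        return (self.linear, self.gate)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.linear.forward(x, train)
        s = sigmoid(self.gate.forward(x, train))
        self._a, self._s = a, s
        return a * s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        a, s = self._a, self._s
        self._a = self._s = None
        dx = self.linear.backward(dy * s)
        dx += self.gate.backward(dy * a * s * (1.0 - s))
        return dx


class LeakyReLU(Layer):
    """y = x for x >= 0, x / divisor otherwise (divisor 100 -> slope 0.01)."""

    def __init__(self, divisor: float = 100.0):
        super().__init__()
        if divisor <= 0:
            raise ModelConfigError("LeakyReLU divisor must be positive")
        self.slope = np.float32(1.0 / divisor)
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, x * self.slope)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, dy * self.slope)


class MaxPool1d(Layer):
    """Non-overlapping max pooling, kernel = stride = 2 (floor division)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        lo = length // 2
        if lo < 1:
            raise ModelConfigError(f"input length {length} too short to pool")
        xv = x[:, :, : 2 * lo].reshape(n, c, lo, 2)
        self._arg = xv.argmax(axis=3)
        self._in_len = length
        return xv.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, lo = dy.shape
        dxv = np.zeros((n, c, lo, 2), dtype=dy.dtype)
        np.put_along_axis(dxv, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=dy.dtype)
        dx[:, :, : 2 * lo] = dxv.reshape(n, c, 2 * lo)
        return dx


class MaxPoolSame3(Layer):
    """Stride-1 max pooling with window 3 and same padding (inception
    pooling branch)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1)), constant_values=-np.inf)
        win = sliding_window_view(xp, 3, axis=2)  # (N, C, L, 3)
        self._arg = win.argmax(axis=3)
        self._len = x.shape[2]
        return win.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = dy.shape
        wins = np.zeros((n, c, length, 3), dtype=dy.dtype)
        np.put_along_axis(wins, self._arg[..., None], dy[..., None], axis=3)
        dxp = np.zeros((n, c, length + 2), dtype=dy.dtype)
        for s in range(3):  # fold overlapping windows back (3 shifted adds)
            dxp[:, :, s : s + length] += wins[:, :, :, s]
        return dxp[:, :, 1 : length + 1]


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ModelConfigError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: Optional[np.random.Generator] = None
        self._mask: Optional[np.ndarray] = None

    def set_rng(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise ModelConfigError("dropout needs an RNG in training mode")
        keep = 1.0 - self.rate
        self._mask = (
            self.rng.random(x.shape) < keep
        ).astype(x.dtype) / np.float32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class BatchNorm1d(Layer):
    """Batch normalization over (batch, features) with learnable scale and
    shift. ``momentum`` is the fraction of the current batch statistic mixed
    into the running statistic each step."""

    def __init__(self, features: int, momentum: float = 0.5, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(features, dtype=np.float32)
        self.beta = np.zeros(features, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.param_names = ["gamma", "beta"]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(features, dtype=np.float32)
        self.running_var = np.ones(features, dtype=np.float32)

    def buffers(self, prefix: str = ""):
        yield f"{prefix}running_mean", self.running_mean
        yield f"{prefix}running_var", self.running_var

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.grads[0] += (dy * xhat).sum(axis=0)
        self.grads[1] += dy.sum(axis=0)
        dxhat = dy * self.gamma
        if not train:
            return dxhat * inv
        n = dy.shape[0]
        return (
            inv / n * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, gain: float = 2.0):
        super().__init__()
        std = np.sqrt(gain / in_features)
        self.W = rng.normal(0.0, std, (in_features, out_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.param_names = ["W", "b"]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T


class SpatialPyramidPool(Layer):
    """1-D spatial pyramid pooling by averaging.

    For each level k the positions are partitioned into k contiguous parts
    whose sizes differ by at most 1; the mean of each part is taken per
    channel, and level outputs are concatenated in ascending level order.
    With levels (1, 2, 4) this yields 7 values per channel regardless of
    input length, which is what lets one parameter set serve every fragment
    length.
    """

    def __init__(self, levels: Sequence[int] = (1, 2, 4)):
        super().__init__()
        if not levels or sorted(levels) != list(levels) or levels[0] != 1:
            raise ModelConfigError(
                "SPP levels must be strictly increasing and include level 1"
            )
        self.levels = tuple(levels)
        self.n_bins = sum(levels)

    @staticmethod
    def _boundaries(length: int, k: int) -> np.ndarray:
        # part sizes ceil(length/k) or floor(length/k); larger parts first
        return np.array(
            [0] + list(np.cumsum([(length + k - 1 - i) // k for i in range(k)]))
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        if length < max(self.levels):
            raise ModelConfigError(
                f"input length {length} shorter than max pyramid level "
                f"{max(self.levels)}"
            )
        pieces = []
        bounds = []
        for k in self.levels:
            cuts = self._boundaries(length, k)
            bounds.append(cuts)
            for i in range(k):
                pieces.append(x[:, :, cuts[i] : cuts[i + 1]].mean(axis=2))
        self._bounds, self._shape = bounds, x.shape
        return np.stack(pieces, axis=2).reshape(n, c * self.n_bins)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dyb = dy.reshape(n, c, self.n_bins)
        dx = np.zeros((n, c, length), dtype=dy.dtype)
        bin_idx = 0
        for k, cuts in zip(self.levels, self._bounds):
            for i in range(k):
                lo, hi = cuts[i], cuts[i + 1]
                dx[:, :, lo:hi] += (dyb[:, :, bin_idx] / (hi - lo))[:, :, None]
                bin_idx += 1
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class InceptionBlock(Layer):
    """Parallel branches applied to the same input, concatenated along the
    channel axis. Every branch preserves length."""

    def __init__(self, *branches: Layer):
        super().__init__()
        self.branches = list(branches)

    def children(self):
        return self.branches

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [b.forward(x, train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        parts = np.split(dy, self._splits, axis=1)
        dx = self.branches[0].backward(np.ascontiguousarray(parts[0]))
        for branch, part in zip(self.branches[1:], parts[1:]):
            dx += branch.backward(np.ascontiguousarray(part))
        return dx
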