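"""Network layers with explicit forward/backward passes.

All layers operate on NHWC float64 batches.  Convolution follows the
deep-learning convention (cross-correlation); pooling uses disjoint 2x2
blocks with floor semantics on odd dimensions.

The functional trio ``conv_forward`` / ``relu`` / ``maxpool2x2`` mirrors the
per-layer contracts on plain 2D matrices and is kept independent of the
batched layer classes so each route can check the other.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..errors import ContractError, SpecError


# ---------------------------------------------------------------------------
# functional single-matrix contracts

def relu(x):
    """Rectified linear unit: max(0, x), elementwise."""
    return np.maximum(0, x)


def maxpool2x2(matrix: np.ndarray) -> np.ndarray:
    """Disjoint 2x2 max pooling of one 2D matrix; odd trailing row/col dropped."""
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ContractError(f"expected a 2D matrix, got ndim={m.ndim}")
    h, w = (m.shape[0] // 2) * 2, (m.shape[1] // 2) * 2
    return m[:h, :w].reshape(h // 2, 2, w // 2, 2).max(axis=(1, 3))


_ACTIVATIONS = {
    "identity": lambda x: x,
    "relu": relu,
    "sigmoid": lambda x: 1.0 / (1.0 + np.exp(-x)),
}


def conv_forward(inputs: Sequence[np.ndarray], kernels: np.ndarray,
                 biases: Sequence[float], activation: str = "identity") -> list[np.ndarray]:
    """Multi-input/multi-output valid convolutional layer on 2D matrices.

    ``kernels[i][j]`` is the kernel pairing input matrix i with output
    matrix j (cross-correlation).  Output j is
    ``f(sum_i inputs[i] * kernels[i][j] + biases[j])``.
    """
    inputs = [np.asarray(I, dtype=np.float64) for I in inputs]
    K = np.asarray(kernels, dtype=np.float64)
    if K.ndim != 4:
        raise ContractError("kernels must have shape (n_in, n_out, k, k)")
    n_in, n_out, kh, kw = K.shape
    if len(inputs) != n_in:
        raise ContractError(f"got {len(inputs)} inputs for {n_in} kernel rows")
    if len(biases) != n_out:
        raise ContractError(f"got {len(biases)} biases for {n_out} outputs")
    f = _ACTIVATIONS[activation]
    H, W = inputs[0].shape
    if any(I.shape != (H, W) for I in inputs):
        raise ContractError("all input matrices must share one shape")
    if kh > H or kw > W:
        raise ContractError("kernel larger than input")
    oh, ow = H - kh + 1, W - kw + 1
    windows = np.stack([np.lib.stride_tricks.sliding_window_view(I, (kh, kw))
                        for I in inputs])  # (n_in, oh, ow, kh, kw)
    outs = []
    for j in range(n_out):
        acc = np.einsum("iabkl,ikl->ab", windows, K[:, j]) + biases[j]
        outs.append(f(acc))
    return outs


# ---------------------------------------------------------------------------
# batched layers

class Layer:
    """Base layer: holds parameters, gradients and a frozen flag."""

    params: list[np.ndarray]
    grads: list[np.ndarray]
    frozen: bool = False

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return 0 if self.frozen else sum(p.size for p in self.params)


class Conv2D(Layer):
    """3x3-style 2D convolution, stride 1, zero 'same' padding, NHWC."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        rng = rng or np.random.default_rng(0)
        fan_in = kernel_size * kernel_size * in_channels
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (kernel_size, kernel_size, in_channels, out_channels))
        b = np.zeros(out_channels)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, train=False):
        W, b = self.params
        n, h, w, c = x.shape
        if c != self.cin:
            raise ContractError(f"expected {self.cin} channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k),
                                                       axis=(1, 2))
        # win: (n, h, w, c, k, k) -> cols (n*h*w, k*k*c) matching W layout
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)
        self._cache = (x.shape, cols)
        out = cols @ W.reshape(-1, self.cout) + b
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout):
        W, _ = self.params
        (n, h, w, c), cols = self._cache
        dflat = dout.reshape(n * h * w, self.cout)
        self.grads[0][...] = (cols.T @ dflat).reshape(W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ W.reshape(-1, self.cout).T).reshape(n, h, w, self.k,
                                                            self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class MaxPool2x2(Layer):
    """Disjoint 2x2 max pooling; odd trailing row/column dropped."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        hh, ww = (h // 2) * 2, (w // 2) * 2
        xc = x[:, :hh, :ww, :].reshape(n, hh // 2, 2, ww // 2, 2, c)
        flat = xc.transpose(0, 1, 3, 5, 2, 4).reshape(n, hh // 2, ww // 2, c, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, h, w, c = self._in_shape
        hh, ww = (h // 2) * 2, (w // 2) * 2
        dflat = np.zeros((n, hh // 2, ww // 2, c, 4))
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None],
                          axis=-1)
        dx = np.zeros((n, h, w, c))
        dx[:, :hh, :ww, :] = dflat.reshape(n, hh // 2, ww // 2, c, 2, 2) \
            .transpose(0, 1, 4, 2, 5, 3).reshape(n, hh, ww, c)
        return dx


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling (decoder mirror of MaxPool2x2)."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer on (n, d) inputs."""

    def __init__(self, in_dim: int, out_dim: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.din, self.dout = in_dim, out_dim
        rng = rng or np.random.default_rng(0)
        W = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim))
        b = np.zeros(out_dim)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, train=False):
        if x.ndim != 2 or x.shape[1] != self.din:
            raise ContractError(f"Dense expected (n,{self.din}), got {x.shape}")
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise SpecError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask
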