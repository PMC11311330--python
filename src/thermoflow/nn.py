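"""Minimal numpy layer library for the package's three small conv nets.

Implements exactly the pieces the pipeline's models need -- stride-1 2-D
convolution ('same' zero padding, via im2col and BLAS matmul), 2x2 max
pooling, nearest-neighbor 2x upsampling, strided 1-D convolution and its
transpose, tanh/relu/dropout, mean-squared-error loss, and the Adam
optimizer. Everything is float32, CPU-only, and deterministic given a
seeded ``numpy.random.Generator`` (dropout masks and shuffling are the
only stochastic parts, and both draw from the generator passed in).

Backward passes are exact: the input gradient of a same-padded conv is the
same-padded conv of the output gradient with the spatially flipped,
channel-transposed kernel; pooling routes gradients through stored argmax
indices.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Adam",
    "Conv2D",
    "MaxPool2D",
    "Upsample2D",
    "Conv1D",
    "ConvTranspose1D",
    "Tanh",
    "ReLU",
    "Dropout",
    "Sequential",
    "fit",
    "predict",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col2d(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix under 'same' zero padding."""
    if k == 1:
        return x.reshape(-1, x.shape[-1])
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        -1, k * k * x.shape[-1]
    )


class Conv2D(Layer):
    """Stride-1 k x k convolution with 'same' zero padding, NHWC layout."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.W = Param(_glorot(rng, (k, k, cin, cout), k * k * cin, k * k * cout))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._shape = x.shape
        self._cols = _im2col2d(x, self.k)
        out = self._cols @ self.W.value.reshape(-1, self.cout) + self.b.value
        return out.reshape(x.shape[0], x.shape[1], x.shape[2], self.cout)

    def backward(self, g):
        gflat = g.reshape(-1, self.cout)
        self.W.grad += (self._cols.T @ gflat).reshape(self.W.value.shape)
        self.b.grad += gflat.sum(axis=0)
        # input gradient = same conv of g with flipped, channel-transposed kernel
        Wt = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,cout,cin)
        cols_g = _im2col2d(g, self.k)
        gx = cols_g @ Wt.reshape(-1, self.cin)
        return gx.reshape(self._shape)


class MaxPool2D(Layer):
    """2x2 max pooling; gradients route through stored argmax indices."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, h, w, c = self._shape
        buf = np.zeros((n, h // 2, w // 2, c, 4), dtype=g.dtype)
        np.put_along_axis(buf, self._idx[..., None], g[..., None], axis=-1)
        return (
            buf.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class Upsample2D(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g):
        n, h, w, c = g.shape
        return g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Conv1D(Layer):
    """Strided 1-D convolution, NLC layout, 'same'-style padding (k-1 total)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        self.cin, self.cout, self.k, self.s = cin, cout, k, stride
        self.W = Param(_glorot(rng, (k, cin, cout), k * cin, k * cout))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._pl = k // 2

    def params(self):
        return [self.W, self.b]

    def out_len(self, L: int) -> int:
        return (L - 1) // self.s + 1

    def forward(self, x, train=False):
        n, L, c = x.shape
        self._L = L
        xp = np.pad(x, ((0, 0), (self._pl, self.k - 1 - self._pl), (0, 0)))
        win = sliding_window_view(xp, self.k, axis=1)  # (n, L, c, k)
        win = win[:, :: self.s]
        lo = win.shape[1]
        self._cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            -1, self.k * c
        )
        out = self._cols @ self.W.value.reshape(-1, self.cout) + self.b.value
        return out.reshape(n, lo, self.cout)

    def backward(self, g):
        n, lo, _ = g.shape
        gflat = g.reshape(-1, self.cout)
        self.W.grad += (self._cols.T @ gflat).reshape(self.W.value.shape)
        self.b.grad += gflat.sum(axis=0)
        gxp = np.zeros((n, self._L + self.k - 1, self.cin), dtype=g.dtype)
        for j in range(self.k):
            gxp[:, j : j + (lo - 1) * self.s + 1 : self.s] += g @ self.W.value[j].T
        return gxp[:, self._pl : self._pl + self._L]


class ConvTranspose1D(Layer):
    """Transposed strided 1-D convolution: output length = input length * stride."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        self.cin, self.cout, self.k, self.s = cin, cout, k, stride
        self.W = Param(_glorot(rng, (k, cin, cout), k * cin, k * cout))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        n, L, c = x.shape
        self._x = x
        full = (L - 1) * self.s + self.k
        y = np.zeros((n, full, self.cout), dtype=x.dtype)
        for j in range(self.k):
            y[:, j : j + (L - 1) * self.s + 1 : self.s] += x @ self.W.value[j]
        cl = (self.k - self.s) // 2
        lout = L * self.s
        return y[:, cl : cl + lout] + self.b.value

    def backward(self, g):
        x = self._x
        n, L, _ = x.shape
        full = (L - 1) * self.s + self.k
        cl = (self.k - self.s) // 2
        gf = np.zeros((n, full, self.cout), dtype=g.dtype)
        gf[:, cl : cl + L * self.s] = g
        self.b.grad += g.sum(axis=(0, 1))
        gx = np.zeros_like(x)
        for j in range(self.k):
            sl = gf[:, j : j + (L - 1) * self.s + 1 : self.s]
            gx += sl @ self.W.value[j].T
            self.W.grad[j] += np.tensordot(x, sl, axes=([0, 1], [0, 1]))
        return gx


class Tanh(Layer):
    def forward(self, x, train=False):
        self._out = np.tanh(x)
        return self._out

    def backward(self, g):
        return g * (1.0 - self._out * self._out)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def count_parameters(model: Layer) -> int:
    return int(sum(p.value.size for p in model.params()))


def predict(model: Layer, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Deterministic inference (dropout disabled), batched."""
    X = np.asarray(X, dtype=np.float32)
    outs = [model.forward(X[s : s + batch_size], train=False) for s in range(0, len(X), batch_size)]
    return np.concatenate(outs, axis=0)


def fit(
    model: Layer,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
    patience: int | None = None,
) -> list[dict]:
    """MSE training loop with Adam; returns per-epoch history.

    ``patience`` enables early stopping on the validation MSE (requires a
    validation set); the history then covers the epochs actually run.
    """
    X = np.asarray(X, dtype=np.float32)
    Y = np.asarray(Y, dtype=np.float32)
    opt = Adam(model.params(), lr=lr)
    history: list[dict] = []
    best = np.inf
    bad = 0
    n = len(X)
    for epoch in range(epochs):
        idx = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            b = idx[s : s + batch_size]
            out = model.forward(X[b], train=True)
            diff = out - Y[b]
            losses.append(float(np.mean(diff * diff)))
            opt.zero_grad()
            model.backward((2.0 / diff.size) * diff)
            opt.step()
        entry = {"epoch": epoch, "train_mse": float(np.mean(losses))}
        if X_val is not None and len(X_val):
            pv = predict(model, X_val, batch_size=batch_size)
            entry["val_mse"] = float(np.mean((pv - Y_val) ** 2))
        history.append(entry)
        if patience is not None and "val_mse" in entry:
            if entry["val_mse"] < best - 1e-12:
                best = entry["val_mse"]
                bad = 0
            else:
                bad += 1
                if bad > patience:
                    break
    return history
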