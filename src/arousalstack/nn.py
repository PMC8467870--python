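"""A small, seeded, CPU-only neural-network core (numpy).

Implements exactly the layer vocabulary the two sequence classifiers need:
valid (no-padding) 1-D convolution, ReLU, length-2 max pooling, global
average pooling, dense layers, and uni/bi-directional LSTM, together with a
softmax cross-entropy head and an Adam optimizer.  Convolutions run in the
frequency domain (rfft of the whole sequence) which is far faster than
im2col for the kernel/length regime used here; gradients are exact
(verified against numerical differentiation in the test suite).

All computation is float32; initialization and batching are driven by an
explicit ``numpy.random.Generator`` so training is deterministic per seed.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft
from scipy.fft import next_fast_len

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "LSTM",
    "Bidirectional",
    "Sequential",
    "softmax",
    "softmax_xent",
    "Adam",
]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # variance-preserving init for ReLU stacks (deep conv chains without
    # normalization starve on Glorot scaling)
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Layer:
    name = "layer"

    def params(self) -> list[tuple[str, Param]]:
        return []

    @property
    def n_params(self) -> int:
        return sum(p.value.size for _, p in self.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape


class Conv1D(Layer):
    """Valid cross-correlation along time: (B, L, Cin) -> (B, L-K+1, Cout)."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "conv"):
        self.kernel, self.c_in, self.c_out = kernel, c_in, c_out
        self.name = name
        self.W = Param(_he(rng, (kernel, c_in, c_out), kernel * c_in))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]

    def out_shape(self, in_shape):
        L, _ = in_shape
        return (L - self.kernel + 1, self.c_out)

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        B, L, _ = x.shape
        nfft = next_fast_len(L)
        Xf = sfft.rfft(x, nfft, axis=1)  # (B, F, Cin)
        Wf = sfft.rfft(self.W.value, nfft, axis=0)  # (F, Cin, Cout)
        Yf = np.matmul(Xf.transpose(1, 0, 2), Wf.conj())  # (F, B, Cout)
        y = sfft.irfft(np.ascontiguousarray(Yf.transpose(1, 0, 2)), nfft, axis=1)
        y = y[:, : L - self.kernel + 1, :]
        if train:
            self._cache = (Xf, Wf, L, nfft)
        return y + self.b.value

    def backward(self, dy):
        Xf, Wf, L, nfft = self._cache
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        DYf = sfft.rfft(dy, nfft, axis=1)  # (B, F, Cout)
        # dW[k,c,o] = sum_{b,t} x[b,t+k,c] dy[b,t,o]  (correlation, lags 0..K-1)
        dWf = np.matmul(Xf.transpose(1, 2, 0), DYf.conj().transpose(1, 0, 2))  # (F,Cin,Cout)
        dW = sfft.irfft(dWf, nfft, axis=0)[: self.kernel]
        # dx[b,n,c] = sum_{k,o} dy[b,n-k,o] W[k,c,o]  (full convolution)
        dXf = np.matmul(DYf.transpose(1, 0, 2), Wf.transpose(0, 2, 1))  # (F, B, Cin)
        dx = sfft.irfft(np.ascontiguousarray(dXf.transpose(1, 0, 2)), nfft, axis=1)[:, :L, :]
        self.W.grad += dW.astype(DTYPE)
        self.b.grad += dy.sum(axis=(0, 1))
        return dx.astype(DTYPE)


class ReLU(Layer):
    name = "relu"

    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """Max pooling, window 2, stride 2; an odd trailing sample is dropped."""

    name = "maxpool"

    def out_shape(self, in_shape):
        L, C = in_shape
        return (L // 2, C)

    def forward(self, x, train=True):
        B, L, C = x.shape
        Lt = (L // 2) * 2
        xr = x[:, :Lt, :].reshape(B, Lt // 2, 2, C)
        idx = xr.argmax(axis=2)
        y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if train:
            self._cache = (idx, x.shape, Lt)
        return y

    def backward(self, dy):
        idx, shape, Lt = self._cache
        B, L, C = shape
        dxr = np.zeros((B, Lt // 2, 2, C), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(shape, dtype=dy.dtype)
        dx[:, :Lt, :] = dxr.reshape(B, Lt, C)
        return dx


class GlobalAvgPool(Layer):
    """Mean over time: (B, L, C) -> (B, C)."""

    name = "gap"

    def out_shape(self, in_shape):
        _, C = in_shape
        return (C,)

    def forward(self, x, train=True):
        if train:
            self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / DTYPE(self._L)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        self.n_in, self.n_out = n_in, n_out
        self.name = name
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]

    def out_shape(self, in_shape):
        return (self.n_out,)

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """Single LSTM layer with gate order (i, f, g, o) and forget bias 1.

    Parameters follow the fused convention: one (D+H, 4H) weight matrix over
    the concatenated [x_t, h_{t-1}] plus a 4H bias, i.e. 4((D+H)H + H)
    trainable parameters.  ``return_sequences`` emits (B, T, H); otherwise
    the final hidden state (B, H).  ``go_backwards`` processes time reversed
    and re-reverses the output so it stays aligned with the input.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False, go_backwards: bool = False,
                 name: str = "lstm"):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self.name = name
        D, H = n_in, n_hidden
        self.W = Param(_glorot(rng, (D + H, 4 * H), D + H, 4 * H))
        b = np.zeros(4 * H, dtype=DTYPE)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.b = Param(b)

    def params(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]

    def out_shape(self, in_shape):
        T, _ = in_shape
        return (T, self.n_hidden) if self.return_sequences else (self.n_hidden,)

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=DTYPE)
        if self.go_backwards:
            x = x[:, ::-1, :]
        B, T, D = x.shape
        H = self.n_hidden
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        cache = []
        W, b = self.W.value, self.b.value
        for t in range(T):
            zcat = np.concatenate([x[:, t, :], h], axis=1)
            gates = zcat @ W + b
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H : 2 * H])
            g = np.tanh(gates[:, 2 * H : 3 * H])
            o = _sigmoid(gates[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t, :] = h
            if train:
                cache.append((zcat, i, f, g, o, c_prev, tc))
        if train:
            self._cache = (cache, x.shape)
        if self.return_sequences:
            return hs[:, ::-1, :] if self.go_backwards else hs
        return h

    def backward(self, dy):
        cache, (B, T, D) = self._cache
        H = self.n_hidden
        W = self.W.value
        if self.return_sequences:
            dhs = dy[:, ::-1, :] if self.go_backwards else dy
        else:
            dhs = None
        dh = np.zeros((B, H), dtype=DTYPE) if dhs is None else np.zeros((B, H), dtype=DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        dW = np.zeros_like(W)
        db = np.zeros_like(self.b.value)
        dx = np.empty((B, T, D), dtype=DTYPE)
        if dhs is None:
            dh = dy.astype(DTYPE).copy()
        for t in range(T - 1, -1, -1):
            zcat, i, f, g, o, c_prev, tc = cache[t]
            if dhs is not None:
                dh = dh + dhs[:, t, :]
            do = dh * tc
            dct = dh * o * (1.0 - tc * tc) + dc
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dc = dct * f
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dW += zcat.T @ dgates
            db += dgates.sum(axis=0)
            dz = dgates @ W.T
            dx[:, t, :] = dz[:, :D]
            dh = dz[:, D:]
        self.W.grad += dW
        self.b.grad += db
        if self.go_backwards:
            dx = dx[:, ::-1, :]
        return dx


class Bidirectional(Layer):
    """Concatenate a forward and a backward LSTM over the feature axis."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator, name: str = "bilstm"):
        self.name = name
        self.fwd = LSTM(n_in, n_hidden, rng, return_sequences=True, name=f"{name}.fwd")
        self.bwd = LSTM(n_in, n_hidden, rng, return_sequences=True, go_backwards=True,
                        name=f"{name}.bwd")
        self.n_hidden = n_hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def out_shape(self, in_shape):
        T, _ = in_shape
        return (T, 2 * self.n_hidden)

    def forward(self, x, train=True):
        return np.concatenate(
            [self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=2
        )

    def backward(self, dy):
        H = self.n_hidden
        return self.fwd.backward(dy[:, :, :H]) + self.bwd.backward(dy[:, :, H:])


class Sequential:
    """A plain layer chain with parameter aggregation and shape tracing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def shape_trace(self, in_shape: tuple) -> list[tuple]:
        shapes = [in_shape]
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
            shapes.append(in_shape)
        return shapes


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits for integer labels."""
    p = softmax(logits.astype(np.float64))
    B = len(y)
    loss = -np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return float(loss), (dlogits / B).astype(DTYPE)


class Adam:
    def __init__(self, params: list[tuple[str, Param]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for _, p in params]
        self.v = [np.zeros_like(p.value) for _, p in params]
        self.t = 0

    def zero_grad(self):
        for _, p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for (name, p), m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
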