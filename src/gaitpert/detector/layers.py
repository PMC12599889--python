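"""NumPy layer primitives with forward/backward passes.

No deep-learning framework is assumed at runtime, so the temporal
convolution, LSTM, dropout and dense layers used by the detector are
implemented here directly on BLAS-backed matrix products.  Activations
are cached per batch for backpropagation (full BPTT for the LSTM).

Array convention: batched sequences are (B, T, C); dense inputs (B, C).
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv1D", "LSTM", "Dropout", "Flatten", "Dense"]


def _sigmoid(x):
    # stable and fast: sigmoid(x) = (tanh(x/2) + 1) / 2
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _glorot_uniform(rng, fan_in, fan_out, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng, shape, dtype):
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q.astype(dtype)


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward.

    Large per-batch work arrays are reused across calls (``_buf``) —
    reallocating tens of MB per step causes allocator page churn that
    dominates runtime on big sequence batches.
    """

    trainable = True

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}
        self._buf: Dict[str, np.ndarray] = {}

    def _get_buf(self, name: str, shape, dtype) -> np.ndarray:
        buf = self._buf.get(name)
        if buf is None or buf.shape != tuple(shape) or buf.dtype != dtype:
            buf = np.empty(shape, dtype=dtype)
            self._buf[name] = buf
        return buf

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def describe(self) -> Dict:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1D(Layer):
    """Temporal convolution, stride 1, 'same' padding, optional ReLU."""

    def __init__(self, in_channels, filters, kernel_size, activation="relu",
                 rng=None, dtype=np.float32):
        super().__init__()
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        self.activation = activation
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.params["W"] = _glorot_uniform(
            rng, fan_in, filters, (fan_in, filters), dtype
        )
        self.params["b"] = np.zeros(filters, dtype=dtype)
        self._cache = None

    def forward(self, x, training=False):
        b, t, c = x.shape
        k = self.kernel_size
        if t < k:
            raise ValueError(f"sequence length {t} < kernel size {k}")
        pl = (k - 1) // 2
        pr = k - 1 - pl
        xp = self._get_buf("xp", (b, t + k - 1, c), x.dtype)
        xp[:, :pl] = 0.0
        xp[:, pl : pl + t] = x
        if pr:
            xp[:, pl + t :] = 0.0
        # (B, T, C, K) view -> (B*T, K*C) @ (K*C, F)
        patches = sliding_window_view(xp, k, axis=1)
        cols = self._get_buf("cols", (b, t, k, c), x.dtype)
        np.copyto(cols, patches.transpose(0, 1, 3, 2))
        cols2 = cols.reshape(b * t, k * c)
        z = self._get_buf("z", (b, t, self.filters), x.dtype)
        np.matmul(cols2, self.params["W"], out=z.reshape(b * t, self.filters))
        z += self.params["b"]
        if self.activation == "relu":
            mask = z > 0
            y = z * mask
        else:
            mask = None
            y = z.copy()
        self._cache = (mask, (b, t, c))
        return y

    def backward(self, dy):
        mask, (b, t, c) = self._cache
        k = self.kernel_size
        cols2 = self._buf["cols"].reshape(b * t, k * c)
        if mask is not None:
            dy = dy * mask
        dy2 = dy.reshape(b * t, self.filters)
        self.grads["W"] = cols2.T @ dy2
        self.grads["b"] = dy2.sum(axis=0)
        dcols = self._get_buf("dcols", (b, t, k, c), dy.dtype)
        np.matmul(dy2, self.params["W"].T, out=dcols.reshape(b * t, k * c))
        pl = (k - 1) // 2
        dxp = self._get_buf("dxp", (b, t + k - 1, c), dy.dtype)
        dxp[:] = 0.0
        for j in range(k):
            dxp[:, j : j + t, :] += dcols[:, :, j, :]
        return dxp[:, pl : pl + t, :].copy()

    def describe(self):
        return {
            "type": "conv1d",
            "filters": self.filters,
            "kernel_size": self.kernel_size,
            "stride": 1,
            "padding": "same",
            "activation": self.activation,
        }


class LSTM(Layer):
    """Single LSTM layer returning the full hidden-state sequence.

    Gate order (i, f, g, o); forget-gate bias initialized to 1.  The input
    projection for all timesteps is computed as one matrix product; only
    the hidden recurrence runs in the timestep loop.
    """

    def __init__(self, in_channels, units, rng=None, dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.units = units
        rng = rng or np.random.default_rng()
        h = units
        self.params["Wx"] = _glorot_uniform(
            rng, in_channels, 4 * h, (in_channels, 4 * h), dtype
        )
        wh = np.concatenate(
            [_orthogonal(rng, (h, h), dtype) for _ in range(4)], axis=1
        )
        self.params["Wh"] = wh
        b = np.zeros(4 * h, dtype=dtype)
        b[h : 2 * h] = 1.0  # forget gate
        self.params["b"] = b
        self._cache = None

    # Internal gate column layout is (i, f, o | g): the three sigmoid gates
    # form one contiguous block so activation runs as a single in-place
    # tanh over it.  Per-step work uses preallocated buffers; only the
    # hidden recurrence h @ Wh stays inside the timestep loop.

    def forward(self, x, training=False):
        b, t, c = x.shape
        h = self.units
        dtype = x.dtype
        wx, wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        # time-major contiguous input, kept for the Wx gradient
        x_t = self._get_buf("x_t", (t, b, c), dtype)
        np.copyto(x_t, x.transpose(1, 0, 2))
        # input projection for all steps as one GEMM
        pre = self._get_buf("pre", (t, b, 4 * h), dtype)
        np.matmul(x_t.reshape(t * b, c), wx, out=pre.reshape(t * b, 4 * h))
        pre += bias
        gates = self._get_buf("gates", (t, b, 4 * h), dtype)  # post-activation
        cs = self._get_buf("cs", (t, b, h), dtype)
        tcs = self._get_buf("tcs", (t, b, h), dtype)
        hs = self._get_buf("hs", (t, b, h), dtype)
        hp = np.zeros((b, h), dtype=dtype)
        tmp = np.empty((b, h), dtype=dtype)
        for ti in range(t):
            g = gates[ti]
            np.matmul(hp, wh, out=g)
            g += pre[ti]
            sig = g[:, : 3 * h]  # i, f, o gates
            sig *= 0.5
            np.tanh(sig, out=sig)
            sig += 1.0
            sig *= 0.5
            zg = g[:, 3 * h :]
            np.tanh(zg, out=zg)
            cell = cs[ti]
            if ti == 0:
                np.multiply(g[:, :h], zg, out=cell)  # i * g (c_prev = 0)
            else:
                np.multiply(g[:, h : 2 * h], cs[ti - 1], out=cell)  # f * c
                np.multiply(g[:, :h], zg, out=tmp)
                cell += tmp
            np.tanh(cell, out=tcs[ti])
            hp = np.multiply(g[:, 2 * h : 3 * h], tcs[ti], out=hs[ti])
        self._cache = (t, b, c)
        return np.ascontiguousarray(hs.transpose(1, 0, 2))

    def backward(self, dy):
        t, b, c = self._cache
        gates, cs, tcs, hs = (
            self._buf["gates"], self._buf["cs"], self._buf["tcs"],
            self._buf["hs"],
        )
        h = self.units
        dtype = dy.dtype
        wh = self.params["Wh"]
        dy_t = self._get_buf("dy_t", (t, b, h), dtype)
        np.copyto(dy_t, dy.transpose(1, 0, 2))
        dz_all = self._get_buf("dz_all", (t, b, 4 * h), dtype)
        dh = np.zeros((b, h), dtype=dtype)
        dc = np.zeros((b, h), dtype=dtype)
        t1 = np.empty((b, h), dtype=dtype)
        t2 = np.empty((b, h), dtype=dtype)
        for ti in range(t - 1, -1, -1):
            g = gates[ti]
            zi = g[:, :h]
            zf = g[:, h : 2 * h]
            zo = g[:, 2 * h : 3 * h]
            zg = g[:, 3 * h :]
            tc = tcs[ti]
            dh += dy_t[ti]
            dz = dz_all[ti]
            # dc += dh * zo * (1 - tc^2)
            np.multiply(tc, tc, out=t1)
            np.subtract(1.0, t1, out=t1)
            t1 *= zo
            t1 *= dh
            dc += t1
            # gate pre-activation gradients (sigmoid': s(1-s); tanh': 1-g^2)
            dzo = dz[:, 2 * h : 3 * h]
            np.multiply(dh, tc, out=dzo)
            np.subtract(1.0, zo, out=t1)
            t1 *= zo
            dzo *= t1
            dzi = dz[:, :h]
            np.multiply(dc, zg, out=dzi)
            np.subtract(1.0, zi, out=t1)
            t1 *= zi
            dzi *= t1
            dzf = dz[:, h : 2 * h]
            if ti > 0:
                np.multiply(dc, cs[ti - 1], out=dzf)
                np.subtract(1.0, zf, out=t1)
                t1 *= zf
                dzf *= t1
            else:
                dzf[:] = 0.0
            dzg = dz[:, 3 * h :]
            np.multiply(dc, zi, out=dzg)
            np.multiply(zg, zg, out=t1)
            np.subtract(1.0, t1, out=t1)
            dzg *= t1
            np.matmul(dz, wh.T, out=dh)
            dc *= zf
        # parameter gradients via batched GEMMs over all timesteps
        dz2 = dz_all.reshape(t * b, 4 * h)
        x_t = self._buf["x_t"].reshape(t * b, c)
        self.grads["Wx"] = x_t.T @ dz2
        self.grads["b"] = dz2.sum(axis=0)
        h_prev = self._get_buf("h_prev", (t, b, h), dtype)
        h_prev[0] = 0.0
        h_prev[1:] = hs[:-1]
        self.grads["Wh"] = h_prev.reshape(t * b, h).T @ dz2
        dx_t = self._get_buf("dx_t", (t, b, c), dtype)
        np.matmul(dz2, self.params["Wx"].T, out=dx_t.reshape(t * b, c))
        return np.ascontiguousarray(dx_t.transpose(1, 0, 2))

    def describe(self):
        return {"type": "lstm", "units": self.units, "return_sequences": True}


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    trainable = False

    def __init__(self, rate, rng=None):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def describe(self):
        return {"type": "dropout", "rate": self.rate}


class Flatten(Layer):
    trainable = False

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def describe(self):
        return {"type": "flatten"}


class Dense(Layer):
    """Fully connected layer; activation in {relu, sigmoid, linear}.

    A sigmoid output layer exposes raw logits to the loss via
    ``logits=True`` on forward, keeping training numerically stable while
    inference still returns probabilities.
    """

    def __init__(self, in_features, units, activation="linear",
                 rng=None, dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.units = units
        self.activation = activation
        rng = rng or np.random.default_rng()
        self.params["W"] = _glorot_uniform(
            rng, in_features, units, (in_features, units), dtype
        )
        self.params["b"] = np.zeros(units, dtype=dtype)
        self._cache = None

    def forward(self, x, training=False, logits=False):
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu" and not logits:
            mask = z > 0
            y = z * mask
        elif self.activation == "sigmoid" and not logits:
            mask = None
            y = _sigmoid(z)
        else:
            mask = None
            y = z
        self._cache = (x, mask, z if self.activation == "sigmoid" else None)
        return y

    def backward(self, dy):
        # NB: for sigmoid output the caller passes d(loss)/d(logit) directly
        x, mask, _ = self._cache
        if mask is not None:
            dy = dy * mask
        self.grads["W"] = x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T

    def describe(self):
        return {
            "type": "dense",
            "units": self.units,
            "activation": self.activation,
        }
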