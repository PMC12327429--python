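"""Minimal NumPy layers with training backprop and attribution multipliers.

Each layer exposes three views of the same computation:

* ``forward(x, training, rng)`` — training-mode pass that caches what the
  gradient pass needs; ``backward(dy)`` then accumulates parameter gradients
  and returns the input gradient.
* ``infer(x)`` — pure inference pass (batch norm uses running statistics,
  dropout is identity).
* ``multipliers(m, x, x_ref, rule)`` — backpropagation of attribution
  multipliers for reference-based contribution scores.  For linear layers the
  multiplier pass equals the inference-mode gradient pass; elementwise
  nonlinearities implement the rescale rule ``(f(x) - f(x_ref)) / (x - x_ref)``
  (``rule="rescale"``) or the plain local derivative (``rule="gradient"``).

Inputs flow as ``(N, E, T)`` arrays and channelized intermediates as
``(N, C, T)`` or ``(N, F, E, T)``.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft


class Layer:
    params: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def infer(self, x):
        return self.forward(x, training=False)

    def backward(self, dy):
        raise NotImplementedError

    def multipliers(self, m, x, x_ref, rule="rescale"):
        """Default: linear layer — multiplier pass equals gradient pass."""
        return self.backward_linear(m)

    def backward_linear(self, dy):
        raise NotImplementedError

    def apply_constraints(self):
        pass


class TemporalConv(Layer):
    """Bank of F1 temporal filters applied to every electrode: (N,E,T)->(N,F1,E,T)."""

    def __init__(self, n_filters: int, kernel_len: int, rng: np.random.Generator):
        super().__init__()
        self.L = int(kernel_len)
        lim = np.sqrt(6.0 / (self.L + n_filters * self.L))
        self.params["W"] = rng.uniform(-lim, lim, size=(n_filters, self.L))

    # All temporal convolutions run as circular FFT products with nfft >= T+L-1
    # (no wraparound); 'same' zero padding realized by index offsets.
    def _plan(self, T):
        L = self.L
        self._T = T
        self._nfft = next_fast_len(T + L - 1)
        self._pl, self._pr = (L - 1) // 2, L // 2

    def forward(self, x, training=False, rng=None):
        W = self.params["W"]
        self._plan(x.shape[-1])
        xf = rfft(x, self._nfft, axis=-1)            # (N,E,nc)
        if training:
            self._xf = xf
        wff = rfft(W[:, ::-1], self._nfft, axis=-1)  # (F,nc)
        y = irfft(xf[:, None, :, :] * wff[None, :, None, :],
                         self._nfft, axis=-1)
        return y[..., self._pr:self._pr + self._T]

    def backward(self, dy):
        W = self.params["W"]
        dyf = rfft(dy, self._nfft, axis=-1)          # (N,F,E,nc)
        corr = np.einsum("nec,nfec->fc", self._xf, np.conj(dyf), optimize=True)
        lags = (np.arange(self.L) - self._pl) % self._nfft
        self.grads["W"] = irfft(corr, self._nfft, axis=-1)[:, lags]
        wf = rfft(W, self._nfft, axis=-1)
        dx = irfft(np.einsum("nfec,fc->nec", dyf, wf, optimize=True),
                          self._nfft, axis=-1)
        return dx[..., self._pl:self._pl + self._T]

    def backward_linear(self, dy):
        self._plan(dy.shape[-1])
        wf = rfft(self.params["W"], self._nfft, axis=-1)
        dyf = rfft(dy, self._nfft, axis=-1)
        dx = irfft(np.einsum("nfec,fc->nec", dyf, wf, optimize=True),
                          self._nfft, axis=-1)
        return dx[..., self._pl:self._pl + self._T]


class DepthwiseSpatial(Layer):
    """Per-temporal-filter spatial filters across electrodes: (N,F,E,T)->(N,F*D,T)."""

    def __init__(self, n_filters: int, depth: int, n_electrodes: int,
                 rng: np.random.Generator, max_norm: float = 1.0):
        super().__init__()
        self.F, self.D, self.E = n_filters, depth, n_electrodes
        self.max_norm = max_norm
        lim = np.sqrt(6.0 / (n_electrodes + depth))
        self.params["W"] = rng.uniform(-lim, lim, size=(n_filters, depth, n_electrodes))

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        y = np.einsum("nfet,fde->nfdt", x, self.params["W"], optimize=True)
        N, F, D, T = y.shape
        return y.reshape(N, F * D, T)

    def backward(self, dy):
        N, _, T = dy.shape
        dyr = dy.reshape(N, self.F, self.D, T)
        self.grads["W"] = np.einsum("nfet,nfdt->fde", self._x, dyr, optimize=True)
        return np.einsum("nfdt,fde->nfet", dyr, self.params["W"], optimize=True)

    def backward_linear(self, dy):
        N, _, T = dy.shape
        dyr = dy.reshape(N, self.F, self.D, T)
        return np.einsum("nfdt,fde->nfet", dyr, self.params["W"], optimize=True)

    def apply_constraints(self):
        W = self.params["W"]
        norms = np.linalg.norm(W, axis=2, keepdims=True)
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        W *= factor


class BatchNorm(Layer):
    """Batch normalization over all axes but the channel axis (axis 1)."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_channels)
        self.params["beta"] = np.zeros(n_channels)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, training=False, rng=None):
        shp = self._bshape(x.ndim)
        if training:
            axes = tuple(i for i in range(x.ndim) if i != 1)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shp)) * invstd.reshape(shp)
            self._cache = (xhat, invstd, axes)
            return self.params["gamma"].reshape(shp) * xhat + self.params["beta"].reshape(shp)
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean.reshape(shp)) * invstd.reshape(shp)
        return self.params["gamma"].reshape(shp) * xhat + self.params["beta"].reshape(shp)

    def backward(self, dy):
        xhat, invstd, axes = self._cache
        shp = self._bshape(dy.ndim)
        m = np.prod([dy.shape[i] for i in axes])
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"].reshape(shp) * invstd.reshape(shp)
        term = dy - dy.mean(axis=axes).reshape(shp) \
            - xhat * (dy * xhat).sum(axis=axes).reshape(shp) / m
        return g * term

    def backward_linear(self, dy):
        # inference mode is a per-channel affine map
        shp = self._bshape(dy.ndim)
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        return dy * (self.params["gamma"] * invstd).reshape(shp)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def _f(self, x):
        return np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))

    def _fprime(self, x):
        return np.where(x > 0, 1.0, self.alpha * np.exp(np.minimum(x, 0.0)))

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        return self._f(x)

    def backward(self, dy):
        return dy * self._fprime(self._x)

    def multipliers(self, m, x, x_ref, rule="rescale"):
        if rule == "gradient":
            return m * self._fprime(x)
        dx = x - x_ref
        small = np.abs(dx) < 1e-7
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (self._f(x) - self._f(x_ref)) / dx
        slope = np.where(small, self._fprime(0.5 * (x + x_ref)), slope)
        return m * slope


class Identity(Layer):
    """Drop-in replacement for the activation, used by linear-network fixtures."""

    def forward(self, x, training=False, rng=None):
        return x

    def backward(self, dy):
        return dy

    def multipliers(self, m, x, x_ref, rule="rescale"):
        return m

    def backward_linear(self, dy):
        return dy


class AvgPool(Layer):
    """Average pooling along the last (time) axis; trailing remainder dropped."""

    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x, training=False, rng=None):
        k = self.k
        T = x.shape[-1]
        Tk = (T // k) * k
        self._T = T
        xr = x[..., :Tk].reshape(x.shape[:-1] + (Tk // k, k))
        return xr.mean(axis=-1)

    def backward(self, dy):
        k = self.k
        out = np.repeat(dy, k, axis=-1) / k
        if out.shape[-1] < self._T:
            pad = [(0, 0)] * (out.ndim - 1) + [(0, self._T - out.shape[-1])]
            out = np.pad(out, pad)
        return out

    def multipliers(self, m, x, x_ref, rule="rescale"):
        self._T = x.shape[-1]
        return self.backward(m)

    def backward_linear(self, dy):
        return self.backward(dy)


class Dropout(Layer):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def multipliers(self, m, x, x_ref, rule="rescale"):
        return m

    def backward_linear(self, dy):
        return dy


class DepthwiseTemporalConv(Layer):
    """Per-channel temporal convolution, 'same' padding: (N,C,T)->(N,C,T)."""

    def __init__(self, n_channels: int, kernel_len: int, rng: np.random.Generator):
        super().__init__()
        self.L = int(kernel_len)
        lim = np.sqrt(6.0 / (2 * self.L))
        self.params["W"] = rng.uniform(-lim, lim, size=(n_channels, self.L))

    def _plan(self, T):
        self._T = T
        self._nfft = next_fast_len(T + self.L - 1)
        self._pl, self._pr = (self.L - 1) // 2, self.L // 2

    def forward(self, x, training=False, rng=None):
        self._plan(x.shape[-1])
        xf = rfft(x, self._nfft, axis=-1)            # (N,C,nc)
        if training:
            self._xf = xf
        wff = rfft(self.params["W"][:, ::-1], self._nfft, axis=-1)
        y = irfft(xf * wff[None], self._nfft, axis=-1)
        return y[..., self._pr:self._pr + self._T]

    def backward(self, dy):
        dyf = rfft(dy, self._nfft, axis=-1)
        corr = (self._xf * np.conj(dyf)).sum(axis=0)        # (C,nc)
        lags = (np.arange(self.L) - self._pl) % self._nfft
        self.grads["W"] = irfft(corr, self._nfft, axis=-1)[:, lags]
        wf = rfft(self.params["W"], self._nfft, axis=-1)
        dx = irfft(dyf * wf[None], self._nfft, axis=-1)
        return dx[..., self._pl:self._pl + self._T]

    def backward_linear(self, dy):
        self._plan(dy.shape[-1])
        wf = rfft(self.params["W"], self._nfft, axis=-1)
        dyf = rfft(dy, self._nfft, axis=-1)
        dx = irfft(dyf * wf[None], self._nfft, axis=-1)
        return dx[..., self._pl:self._pl + self._T]


class PointwiseConv(Layer):
    """1x1 channel-mixing convolution: (N,Cin,T)->(N,Cout,T)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        lim = np.sqrt(6.0 / (c_in + c_out))
        self.params["W"] = rng.uniform(-lim, lim, size=(c_out, c_in))

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        return np.einsum("nct,oc->not", x, self.params["W"], optimize=True)

    def backward(self, dy):
        self.grads["W"] = np.einsum("nct,not->oc", self._x, dy, optimize=True)
        return np.einsum("not,oc->nct", dy, self.params["W"], optimize=True)

    def backward_linear(self, dy):
        return np.einsum("not,oc->nct", dy, self.params["W"], optimize=True)


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def multipliers(self, m, x, x_ref, rule="rescale"):
        return m.reshape(x.shape)

    def backward_linear(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 max_norm: float | None = 0.25):
        super().__init__()
        lim = np.sqrt(6.0 / (d_in + d_out))
        self.params["W"] = rng.uniform(-lim, lim, size=(d_out, d_in))
        self.params["b"] = np.zeros(d_out)
        self.max_norm = max_norm

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]

    def backward_linear(self, dy):
        return dy @ self.params["W"]

    def apply_constraints(self):
        if self.max_norm is None:
            return
        W = self.params["W"]
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        W *= np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
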