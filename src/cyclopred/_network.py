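"""Compact NumPy implementation of a stacked-LSTM regressor.

Three (configurable) LSTM layers followed by a dense head that reads the
last hidden state; trained with mean-squared error and Adam.  The
implementation is deliberately minimal but numerically standard:

* gate order ``i, f, g, o`` with a unit forget-gate bias at init,
* Glorot-uniform input kernels, orthogonal recurrent kernels,
* full backpropagation through time (no truncation),
* float32 by default for speed; float64 available for gradient checks.

Internally sequences are handled time-major, (T, B, features), so every
per-timestep slice is contiguous; the gate cache shares storage with the
input projections.  Everything is driven by a seeded
:class:`numpy.random.Generator`, so runs are reproducible bit-for-bit on
a fixed BLAS configuration.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMRegressor", "Adam"]


def _sigmoid_(x):
    """In-place logistic function."""
    np.negative(x, out=x)
    np.exp(x, out=x)
    x += 1.0
    np.reciprocal(x, out=x)
    return x


def _glorot(rng, shape, dtype):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng, n, m, dtype):
    """Orthogonal (n, m) block, column-orthonormal per gate."""
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    q = q if n >= m else q.T
    return q[:n, :m].astype(dtype)


class LSTMRegressor:
    """Stacked LSTM layers + dense head mapping (B, T, n_in) -> (B, n_out)."""

    def __init__(self, n_in: int, units: tuple[int, ...], n_out: int,
                 seed: int = 0, dtype=np.float32):
        self.n_in = int(n_in)
        self.units = tuple(int(u) for u in units)
        self.n_out = int(n_out)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: list[np.ndarray] = []
        fan_in = self.n_in
        self._layers = []
        for h in self.units:
            Wx = _glorot(rng, (fan_in, 4 * h), self.dtype)
            Wh = np.concatenate(
                [_orthogonal(rng, h, h, self.dtype) for _ in range(4)], axis=1)
            b = np.zeros(4 * h, dtype=self.dtype)
            b[h:2 * h] = 1.0          # forget-gate bias
            self._layers.append((Wx, Wh, b))
            self.params += [Wx, Wh, b]
            fan_in = h
        Wd = _glorot(rng, (fan_in, self.n_out), self.dtype)
        bd = np.zeros(self.n_out, dtype=self.dtype)
        self._dense = (Wd, bd)
        self.params += [Wd, bd]

    # -- forward -----------------------------------------------------------

    def _layer_forward(self, X, Wx, Wh, b):
        """X is time-major (T, B, n).  Returns (Hs, gate cache, C, TC)."""
        T, B, _ = X.shape
        H = Wh.shape[0]
        # input projections for the whole sequence in one product; the
        # same buffer later holds the gate activations (i, f, g, o)
        Z = (X.reshape(T * B, -1) @ Wx).reshape(T, B, 4 * H)
        Z += b
        h = np.zeros((B, H), self.dtype)
        c = np.zeros((B, H), self.dtype)
        Hs = np.empty((T, B, H), self.dtype)
        C = np.empty((T, B, H), self.dtype)
        TC = np.empty((T, B, H), self.dtype)
        for t in range(T):
            z = Z[t]
            z += h @ Wh
            _sigmoid_(z[:, :2 * H])
            _sigmoid_(z[:, 3 * H:])
            np.tanh(z[:, 2 * H:3 * H], out=z[:, 2 * H:3 * H])
            i, f = z[:, :H], z[:, H:2 * H]
            g, o = z[:, 2 * H:3 * H], z[:, 3 * H:]
            c = f * c
            c += i * g
            tc = np.tanh(c)
            h = o * tc
            C[t] = c
            TC[t] = tc
            Hs[t] = h
        return Hs, Z, C, TC

    def forward(self, X, cache: bool = False):
        """Run the network; X is (B, T, n_in).  Returns (B, n_out)."""
        X = np.ascontiguousarray(
            np.asarray(X, dtype=self.dtype).transpose(1, 0, 2))
        caches = []
        inp = X
        for (Wx, Wh, b) in self._layers:
            Hs, Z, C, TC = self._layer_forward(inp, Wx, Wh, b)
            caches.append((inp, Hs, Z, C, TC))
            inp = Hs
        Wd, bd = self._dense
        out = inp[-1] @ Wd + bd
        if cache:
            self._cache = (caches, inp[-1])
        return out

    # -- backward ----------------------------------------------------------

    def _layer_backward(self, dHs, cache, Wx, Wh):
        """dHs: upstream gradient on Hs, time-major; consumes the cache."""
        X, Hs, Z, C, TC = cache
        T, B, H = Hs.shape
        dh = np.zeros((B, H), self.dtype)
        dc = np.zeros((B, H), self.dtype)
        for t in range(T - 1, -1, -1):
            z = Z[t]
            i, f = z[:, :H], z[:, H:2 * H]
            g, o = z[:, 2 * H:3 * H], z[:, 3 * H:]
            tc = TC[t]
            dh = dh + dHs[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            c_prev = C[t - 1] if t > 0 else 0.0
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc *= f
            # overwrite the gate cache with the pre-activation deltas
            g *= g
            np.subtract(1.0, g, out=g)
            g *= dg
            i -= i * i
            i *= di
            f -= f * f
            f *= df
            o -= o * o
            o *= do
            dh = z @ Wh.T
        dZ = Z
        # h_{-1} is zero, so the recurrent-kernel gradient collapses to one
        # product of the shifted hidden sequence with the gate deltas
        dWh = (Hs[: T - 1].reshape((T - 1) * B, H).T
               @ dZ[1:].reshape((T - 1) * B, 4 * H))
        flatX = X.reshape(T * B, -1)
        flatZ = dZ.reshape(T * B, -1)
        dWx = flatX.T @ flatZ
        db = flatZ.sum(axis=0)
        dX = (flatZ @ Wx.T).reshape(X.shape)
        return dX, dWx, dWh, db

    def backward(self, dOut):
        """Gradients of all params for upstream gradient dOut (B, n_out)."""
        caches, last_h = self._cache
        Wd, bd = self._dense
        dOut = np.asarray(dOut, dtype=self.dtype)
        dWd = last_h.T @ dOut
        dbd = dOut.sum(axis=0)
        dLast = dOut @ Wd.T
        grads: list[np.ndarray] = []
        dHs = None
        for li in range(len(self._layers) - 1, -1, -1):
            Wx, Wh, b = self._layers[li]
            if dHs is None:
                dHs = np.zeros_like(caches[li][1])
                dHs[-1] = dLast
            dX, dWx, dWh, db = self._layer_backward(dHs, caches[li], Wx, Wh)
            grads = [dWx, dWh, db] + grads
            dHs = dX
        grads += [dWd, dbd]
        del self._cache
        return grads

    @staticmethod
    def residual(out, Y, circular_channels=()):
        """Prediction residual; circular channels are wrapped to their
        principal value (period 2 in channel units) so an angle target is
        penalised by the minimal circular difference."""
        err = out - np.asarray(Y, dtype=out.dtype)
        for ch in circular_channels:
            err[:, ch] = np.mod(err[:, ch] + 1.0, 2.0) - 1.0
        return err

    def train_step(self, X, Y, opt: "Adam", circular_channels=(),
                   channel_weights=None) -> float:
        """One (weighted) MSE minibatch step; returns the batch loss."""
        out = self.forward(X, cache=True)
        err = self.residual(out, np.asarray(Y, dtype=self.dtype),
                            circular_channels)
        w = 1.0 if channel_weights is None else np.asarray(
            channel_weights, dtype=self.dtype)
        loss = float(np.mean(w * err * err))
        dOut = (2.0 / err.size) * w * err
        grads = self.backward(dOut)
        opt.step(self.params, grads)
        return loss

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{k}": p for k, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in enumerate(self.params):
            new = state[f"param_{k}"]
            if new.shape != p.shape:
                raise ValueError(f"param {k}: shape {new.shape} != {p.shape}")
            p[...] = new.astype(self.dtype)


class Adam:
    """Adam optimiser with the usual bias-corrected moment estimates."""

    def __init__(self, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            g = g.astype(p.dtype, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= (self.lr * corr) * m / (np.sqrt(v) + self.eps)
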