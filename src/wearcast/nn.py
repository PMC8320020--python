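"""A compact seeded LSTM regressor for the 7-day sleep history.

The daily sleep model maps a 7 x 7 array (seven prior nights, seven sleep
features per night) to a seizure likelihood for the coming day.  The network
is a single LSTM layer (64 memory units by default) followed by two dense
layers with a linear output, trained with mean-squared-error loss and the
Adam optimizer for 100 epochs.  Implemented directly on numpy with full
backpropagation through time; weights, batching and training are pure
functions of the seed, so fits are bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class SleepLSTM:
    """LSTM -> dense(relu) -> dense(1, linear), MSE loss, Adam optimizer.

    Parameters
    ----------
    units : LSTM memory units.
    dense_units : width of the intermediate dense layer.
    epochs : training epochs (full passes, mini-batches of ``batch_size``).
    lr : Adam step size.
    seed : seeds weight initialization and batch shuffling.
    """

    def __init__(self, units: int = 64, dense_units: int = 32, epochs: int = 100,
                 lr: float = 1e-3, batch_size: int = 32, seed: int = 0):
        self.units = units
        self.dense_units = dense_units
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self._params = None
        self._constant = None
        self._norm = None

    # -- parameter handling -------------------------------------------------

    def _init_params(self, n_features: int, rng) -> dict:
        u, d = self.units, self.dense_units

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, shape)

        b = np.zeros(4 * u)
        b[u:2 * u] = 1.0                      # forget-gate bias at 1
        return {
            "Wx": glorot(n_features, u, (n_features, 4 * u)),
            "Wh": glorot(u, u, (u, 4 * u)),
            "b": b,
            "W1": glorot(u, d, (u, d)),
            "b1": np.zeros(d),
            "W2": glorot(d, 1, (d, 1)),
            "b2": np.zeros(1),
        }

    # -- forward / backward -------------------------------------------------

    def _forward(self, X, params, cache: bool = False):
        B, T, D = X.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        steps = []
        for t in range(T):
            z = X[:, t] @ params["Wx"] + h @ params["Wh"] + params["b"]
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            if cache:
                steps.append((X[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        a1 = h @ params["W1"] + params["b1"]
        y1 = np.maximum(a1, 0.0)
        out = (y1 @ params["W2"] + params["b2"]).ravel()
        if cache:
            return out, (steps, h, a1, y1)
        return out

    def _backward(self, X, y, params):
        B = X.shape[0]
        u = self.units
        out, (steps, hT, a1, y1) = self._forward(X, params, cache=True)
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dout = (2.0 / B) * (out - y)[:, None]
        grads["W2"] = y1.T @ dout
        grads["b2"] = dout.sum(axis=0)
        dy1 = dout @ params["W2"].T
        dy1[a1 <= 0] = 0.0
        grads["W1"] = hT.T @ dy1
        grads["b1"] = dy1.sum(axis=0)
        dh = dy1 @ params["W1"].T
        dc = np.zeros_like(dh)
        for x_t, h_prev, c_prev, i, f, g, o, c_new in reversed(steps):
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * f
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g * g), do * o * (1 - o)], axis=1)
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ params["Wh"].T
            dc = dc_prev
        loss = float(np.mean((out - y) ** 2))
        return loss, grads

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SleepLSTM":
        """Train on sleep-history tensors X (n, days, features) and 0/1 labels."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, n_days, n_features)")
        if len(np.unique(y)) < 2:
            warnings.warn("sleep-model labels contain a single class; "
                          "fitting a constant at the class rate")
            self._constant = float(y.mean()) if y.size else 0.0
            return self
        self._constant = None
        # standardize per feature over samples and days (fit on training data)
        mu = X.mean(axis=(0, 1))
        sd = X.std(axis=(0, 1))
        sd[sd == 0] = 1.0
        self._norm = (mu, sd)
        Xn = (X - mu) / sd

        rng = np.random.default_rng(self.seed)
        params = self._init_params(X.shape[2], rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = X.shape[0]
        bs = min(self.batch_size, n)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, bs):
                idx = order[s:s + bs]
                _, grads = self._backward(Xn[idx], y[idx], params)
                step += 1
                for k in params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1 ** step)
                    vh = v[k] / (1 - b2 ** step)
                    params[k] -= self.lr * mh / (np.sqrt(vh) + eps)
        self._params = params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Seizure likelihoods in [0, 1], one per sleep-history tensor."""
        X = np.asarray(X, dtype=float)
        if self._constant is not None:
            return np.full(X.shape[0], self._constant)
        if self._params is None:
            raise RuntimeError("model is not fitted")
        mu, sd = self._norm
        out = self._forward((X - mu) / sd, self._params)
        return np.clip(out, 0.0, 1.0)
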