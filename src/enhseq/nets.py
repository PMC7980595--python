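"""A small numpy neural-network engine for the three classifier families.

Implements exactly what the enhancer classifiers need — dense, 1-D
convolution, max pooling, dropout and a bidirectional LSTM, trained with Adam
on a binary cross-entropy (with-logits) loss and early stopping on validation
loss — for laptop-scale CPU training on L x |K| positional fold-change
arrays.  Inputs are (N, L, C) arrays with C channels (one per k-mer size);
every network emits a single logit per sample.

All layers expose ``forward(x, train)`` / ``backward(grad)`` and matched
``params`` / ``grads`` lists; gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits)."""
    z = logits.reshape(-1)
    y = y.reshape(-1).astype(np.float64)
    # log(1 + e^z) computed stably
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (_sigmoid(z) - y) / len(z)
    return loss, grad.reshape(logits.shape)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv1D(Layer):
    """Valid 1-D convolution over the position axis of (N, L, C) inputs."""

    def __init__(self, n_in: int, n_filters: int, width: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.width = width
        self.n_in = n_in
        fan_in = width * n_in
        self.W = _glorot(rng, fan_in, n_filters, (fan_in, n_filters))
        self.b = np.zeros(n_filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        N, L, C = x.shape
        w = self.width
        if L < w:
            raise ValueError(f"input length {L} shorter than filter width {w}")
        # (N, Lout, C, w) -> (N, Lout, w, C) -> (N*Lout, w*C)
        cols = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))
        self._cols = cols.reshape(N * (L - w + 1), w * C)
        self._in_shape = (N, L, C)
        out = self._cols @ self.W + self.b
        return out.reshape(N, L - w + 1, -1)

    def backward(self, grad):
        N, L, C = self._in_shape
        w = self.width
        Lout = L - w + 1
        g = grad.reshape(N * Lout, -1)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(N, Lout, w, C)
        dx = np.zeros((N, L, C))
        for t in range(w):
            dx[:, t:t + Lout, :] += dcols[:, :, t, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling over positions; trailing remainder dropped."""

    def __init__(self, width: int = 2) -> None:
        super().__init__()
        self.width = width

    def forward(self, x, train=False):
        N, L, C = x.shape
        w = self.width
        Lout = L // w
        xt = x[:, :Lout * w, :].reshape(N, Lout, w, C)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, grad):
        N, L, C = self._in_shape
        w = self.width
        Lout = L // w
        dx = np.zeros((N, Lout, w, C))
        n_idx, l_idx, c_idx = np.ogrid[:N, :Lout, :C]
        dx[n_idx, l_idx, self._argmax, c_idx] = grad
        out = np.zeros(self._in_shape)
        out[:, :Lout * w, :] = dx.reshape(N, Lout * w, C)
        return out


class GlobalMaxPool(Layer):
    def forward(self, x, train=False):
        self._argmax = x.argmax(axis=1)
        self._in_shape = x.shape
        return x.max(axis=1)

    def backward(self, grad):
        N, L, C = self._in_shape
        dx = np.zeros(self._in_shape)
        n_idx, c_idx = np.ogrid[:N, :C]
        dx[n_idx, self._argmax, c_idx] = grad
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM over positions; outputs concatenated final hidden
    states, (N, 2 * units).  Forget-gate bias initialized to 1."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in = n_in
        self.units = units
        self.params = []
        self.grads = []
        for _ in range(2):  # forward, backward direction
            Wx = _glorot(rng, n_in, units, (n_in, 4 * units))
            Wh = _glorot(rng, units, units, (units, 4 * units))
            b = np.zeros(4 * units)
            b[units:2 * units] = 1.0  # forget gate
            self.params += [Wx, Wh, b]
            self.grads += [np.zeros_like(Wx), np.zeros_like(Wh), np.zeros_like(b)]

    def _run(self, x: np.ndarray, d: int) -> tuple[np.ndarray, dict]:
        Wx, Wh, b = self.params[3 * d:3 * d + 3]
        N, T, _ = x.shape
        H = self.units
        order = range(T) if d == 0 else range(T - 1, -1, -1)
        order = list(order)
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        cache = {"i": [], "f": [], "g": [], "o": [], "c": [], "tc": [],
                 "h_prev": [], "c_prev": [], "order": order}
        for t in order:
            z = x[:, t, :] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            cache["h_prev"].append(h)
            cache["c_prev"].append(c)
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            for key, val in (("i", i), ("f", f), ("g", g), ("o", o),
                             ("c", c), ("tc", tc)):
                cache[key].append(val)
        return h, cache

    def forward(self, x, train=False):
        self._x = x
        h_fwd, self._cache_fwd = self._run(x, 0)
        h_bwd, self._cache_bwd = self._run(x, 1)
        return np.concatenate([h_fwd, h_bwd], axis=1)

    def _back_dir(self, dh_final: np.ndarray, d: int, cache: dict,
                  dx: np.ndarray) -> None:
        Wx, Wh, _ = self.params[3 * d:3 * d + 3]
        gWx, gWh, gb = self.grads[3 * d:3 * d + 3]
        x = self._x
        H = self.units
        dh = dh_final
        dc = np.zeros_like(dh)
        for step in range(len(cache["order"]) - 1, -1, -1):
            t = cache["order"][step]
            i, f, g, o = (cache[k][step] for k in ("i", "f", "g", "o"))
            tc = cache["tc"][step]
            c_prev = cache["c_prev"][step]
            h_prev = cache["h_prev"][step]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            gWx += x[:, t, :].T @ dz
            gWh += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dx[:, t, :] += dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f

    def backward(self, grad):
        H = self.units
        dx = np.zeros_like(self._x)
        for g in self.grads:
            g[...] = 0.0
        self._back_dir(grad[:, :H], 0, self._cache_fwd, dx)
        self._back_dir(grad[:, H:], 1, self._cache_bwd, dx)
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def train_network(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 50,
    patience: int = 5,
    min_delta: float = 1e-3,
) -> dict:
    """Mini-batch Adam training with early stopping on validation loss.

    An epoch counts as an improvement only if it beats the best validation
    loss by at least ``min_delta``; after ``patience`` non-improving epochs
    training stops.  The weights giving the best validation loss are restored
    before returning.  Returns a history dict with per-epoch train/val losses and
    the epoch restored.
    """
    opt = Adam(net.params, lr=lr)
    n = len(X)
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = -1
    history: dict = {"train_loss": [], "val_loss": []}
    since_best = 0
    for epoch in range(max_epochs):
        perm = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, batch_size):
            idx = perm[lo:lo + batch_size]
            logits = net.forward(X[idx], train=True)
            loss, dlog = bce_with_logits(logits, y[idx])
            net.backward(dlog)
            opt.step(net.grads)
            total += loss * len(idx)
        val_logits = net.forward(X_val, train=False)
        val_loss, _ = bce_with_logits(val_logits, y_val)
        history["train_loss"].append(total / n)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            # checkpoint any strict improvement ...
            best_weights = net.get_weights()
            best_epoch = epoch
        if val_loss < best_val - min_delta:
            # ... but only a meaningful one resets the patience counter
            since_best = 0
        else:
            since_best += 1
        best_val = min(best_val, val_loss)
        if since_best >= patience:
            break
    net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return history
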