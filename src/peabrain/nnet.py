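"""Minimal seeded neural-network engine: 1D valid convolutions, max pooling,
dropout, dense layers, leaky-rectify activations, Adam, and an early-exit
training loop.

All arrays are float32, batch-first: ``(batch, length, channels)`` for
sequence layers and ``(batch, features)`` after flattening.  Every source of
randomness (weight init, shuffling, dropout) is drawn from an explicit
``numpy.random.Generator`` so training is bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "leaky_rectify",
    "Conv1D",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "train_loop",
]


def leaky_rectify(x, slope: float = 0.01):
    """f(x) = x for x > 0, slope*x otherwise (slope = "leakiness")."""
    x = np.asarray(x)
    return np.where(x > 0, x, slope * x)


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D:
    """Valid (unpadded) 1D convolution with ``n_filters`` kernels of a given
    width, optionally followed by a leaky-rectify non-linearity."""

    def __init__(self, in_channels, n_filters=11, width=5, activation="leaky",
                 slope=0.01, *, rng):
        self.in_channels = in_channels
        self.n_filters = n_filters
        self.width = width
        self.activation = activation
        self.slope = slope
        fan_in = width * in_channels
        self.W = _glorot_uniform(rng, fan_in, n_filters, (width * in_channels, n_filters))
        self.b = np.zeros(n_filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_length(self, L):
        out = L - self.width + 1
        if out < 1:
            raise ValueError(
                f"input length {L} too short for conv width {self.width}")
        return out

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        Lout = self.out_length(L)
        cols = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        # (B, Lout, C, width) -> (B*Lout, width*C)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B * Lout, -1)
        z = (cols @ self.W + self.b).reshape(B, Lout, self.n_filters)
        self._cols = cols
        self._z = z if self.activation == "leaky" else None
        self._in_shape = (B, L, C)
        if self.activation == "leaky":
            return leaky_rectify(z, self.slope)
        return z

    def backward(self, grad):
        B, L, C = self._in_shape
        Lout = grad.shape[1]
        if self.activation == "leaky":
            grad = np.where(self._z > 0, grad, self.slope * grad)
        g2 = grad.reshape(B * Lout, self.n_filters)
        self.dW[...] = self._cols.T @ g2
        self.db[...] = g2.sum(axis=0)
        dx = np.zeros((B, L, C), dtype=grad.dtype)
        Wk = self.W.reshape(self.width, C, self.n_filters)
        for i in range(self.width):
            dx[:, i:i + Lout, :] += grad @ Wk[i].T
        self._cols = None
        self._z = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool1D:
    """Non-overlapping max pooling; a trailing remainder shorter than the
    pool size is truncated."""

    def __init__(self, size):
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size

    def out_length(self, L):
        out = L // self.size
        if out < 1:
            raise ValueError(f"input length {L} too short for pool size {self.size}")
        return out

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        n = self.out_length(L)
        xv = x[:, : n * self.size].reshape(B, n, self.size, C)
        self._argmax = xv.argmax(axis=2)
        self._in_shape = (B, L, C)
        return xv.max(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        n = grad.shape[1]
        dx = np.zeros((B, n, self.size, C), dtype=grad.dtype)
        np.put_along_axis(dx, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        out = np.zeros((B, L, C), dtype=grad.dtype)
        out[:, : n * self.size] = dx.reshape(B, n * self.size, C)
        return out

    def params(self):
        return []


class Dropout:
    """Inverted dropout: active only in training mode; inference is the
    identity, so forward passes at prediction time are deterministic."""

    def __init__(self, p=0.5):
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask

    def params(self):
        return []


class Flatten:
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, in_features, out_features, activation="linear",
                 slope=0.01, *, rng):
        self.in_features = in_features
        self.out_features = out_features
        self.activation = activation
        self.slope = slope
        self.W = _glorot_uniform(rng, in_features, out_features,
                                 (in_features, out_features))
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        z = x @ self.W + self.b
        self._x = x
        self._z = z if self.activation == "leaky" else None
        if self.activation == "leaky":
            return leaky_rectify(z, self.slope)
        return z

    def backward(self, grad):
        if self.activation == "leaky":
            grad = np.where(self._z > 0, grad, self.slope * grad)
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        dx = grad @ self.W.T
        self._x = None
        self._z = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights):
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(params, weights):
            p[...] = w


class Adam:
    """Adam optimizer (Kingma & Ba) with the conventional bias correction."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def mse_and_grad(pred, y):
    pred = pred.reshape(-1)
    diff = pred - y
    loss = float(np.mean(diff ** 2))
    grad = (2.0 / len(y)) * diff
    return loss, grad.reshape(-1, 1)


def train_loop(model, batch_fn, val_x, val_y, *, optimizer, rng,
               min_epochs=100, patience=20, max_epochs=None):
    """Generic MSE training loop with early exit on a fixed validation set.

    ``batch_fn(rng)`` yields ``(xb, yb)`` minibatches for one epoch.  Training
    runs for at least ``min_epochs`` epochs; after that it stops once the
    validation loss has not improved for ``patience`` consecutive epochs.  The
    model is restored to the best-validation checkpoint before returning.

    Returns the training log, a list of ``(epoch, train_loss, val_loss)``.
    """
    if max_epochs is None:
        max_epochs = min_epochs * 10
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    log = []
    for epoch in range(max_epochs):
        losses = []
        for xb, yb in batch_fn(rng):
            pred = model.forward(xb, train=True, rng=rng)
            loss, grad = mse_and_grad(pred, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            model.backward(grad)
            optimizer.step()
            losses.append(loss)
        val_pred = model.forward(val_x, train=False)
        val_loss, _ = mse_and_grad(val_pred, val_y)
        log.append((epoch, float(np.mean(losses)), val_loss))
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
        if epoch + 1 >= min_epochs and since_best >= patience:
            break
    model.set_weights(best_weights)
    return log
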