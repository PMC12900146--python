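"""A compact numpy convolutional network for patch-based regression.

The network regresses a single real target (SOM, g/kg) from a 7x7xC input
patch with the fixed shallow architecture

    conv 3x3 x32 ReLU -> maxpool 2x2 -> conv 2x2 x48 ReLU -> dropout 0.2
    -> conv 2x2 x24 ReLU -> conv 2x2 x12 ReLU -> dropout 0.2 -> flatten
    -> dense 80 ReLU -> dropout 0.1 -> dense 15 ReLU -> dense 1 linear

trained with Adam on a mean-squared-error loss. Convolutions use valid
padding; the max-pool uses a stride of 1 so the 2x2 convolution chain
shrinks 7 -> 5 -> 4 -> 3 -> 2 -> 1 without dimension underflow. Dropout is
inverted and active only during training, so inference is deterministic.
All randomness (weight init, shuffling, dropout masks) flows from one seed.

The implementation is deliberately minimal — dense/convolution forward and
backward passes are written against numpy directly and validated by a
numerical gradient check in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CnnRegressor", "CNN_ARCHITECTURE"]

# (layer type, parameters) in order; mirrored by _build()
CNN_ARCHITECTURE = [
    ("conv", {"kernel": 3, "filters": 32, "activation": "relu"}),
    ("maxpool", {"size": 2, "stride": 1}),
    ("conv", {"kernel": 2, "filters": 48, "activation": "relu"}),
    ("dropout", {"rate": 0.2}),
    ("conv", {"kernel": 2, "filters": 24, "activation": "relu"}),
    ("conv", {"kernel": 2, "filters": 12, "activation": "relu"}),
    ("dropout", {"rate": 0.2}),
    ("flatten", {}),
    ("dense", {"units": 80, "activation": "relu"}),
    ("dropout", {"rate": 0.1}),
    ("dense", {"units": 15, "activation": "relu"}),
    ("dense", {"units": 1, "activation": "linear"}),
]


class _Conv:
    def __init__(self, kernel: int, cin: int, cout: int, activation: str, rng):
        fan_in = kernel * kernel * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, cin, cout))
        self.b = np.zeros(cout)
        self.k = kernel
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training, rng):
        self.x = x
        n, h, w, cin = x.shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        out = np.zeros((n, oh, ow, self.W.shape[-1]))
        for a in range(k):
            for b in range(k):
                out += np.tensordot(x[:, a:a + oh, b:b + ow, :], self.W[a, b], axes=1)
        out += self.b
        if self.activation == "relu":
            self.pre = out
            out = np.maximum(out, 0.0)
        return out

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * (self.pre > 0)
        x = self.x
        n, h, w, cin = x.shape
        k = self.k
        oh, ow = dout.shape[1], dout.shape[2]
        self.dW = np.zeros_like(self.W)
        self.db = dout.sum(axis=(0, 1, 2))
        dx = np.zeros_like(x)
        for a in range(k):
            for b in range(k):
                patch = x[:, a:a + oh, b:b + ow, :]
                self.dW[a, b] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dx[:, a:a + oh, b:b + ow, :] += np.tensordot(dout, self.W[a, b].T, axes=1)
        return dx

    def grads(self):
        return [self.dW, self.db]


class _MaxPool:
    """2x2 max pooling with configurable stride (overlapping when stride 1)."""

    def __init__(self, size: int, stride: int):
        self.size = size
        self.stride = stride

    def params(self):
        return []

    def forward(self, x, training, rng):
        self.x = x
        s, k = self.stride, self.size
        n, h, w, c = x.shape
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        windows = np.stack([x[:, a + np.arange(oh)[:, None] * s,
                              b + np.arange(ow)[None, :] * s, :]
                            for a in range(k) for b in range(k)])  # (k*k, n, oh, ow, c)
        self.windows_shape = (oh, ow)
        self.argmax = np.argmax(windows, axis=0)
        return np.max(windows, axis=0)

    def backward(self, dout):
        s, k = self.stride, self.size
        oh, ow = self.windows_shape
        dx = np.zeros_like(self.x)
        for idx in range(k * k):
            a, b = divmod(idx, k)
            sel = (self.argmax == idx) * dout
            dx[:, a + np.arange(oh)[:, None] * s, b + np.arange(ow)[None, :] * s, :] += sel
        return dx

    def grads(self):
        return []


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def params(self):
        return []

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (rng.random(x.shape) < keep) / keep
        return x * self.mask

    def backward(self, dout):
        return dout if self.mask is None else dout * self.mask

    def grads(self):
        return []


class _Flatten:
    def params(self):
        return []

    def forward(self, x, training, rng):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.shape)

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, units: int, activation: str, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, units))
        self.b = np.zeros(units)
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training, rng):
        self.x = x
        out = x @ self.W + self.b
        if self.activation == "relu":
            self.pre = out
            out = np.maximum(out, 0.0)
        return out

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * (self.pre > 0)
        self.dW = self.x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def grads(self):
        return [self.dW, self.db]


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class CnnRegressor:
    """Seeded shallow CNN regressor on (n, 7, 7, C) patches.

    Inputs are expected pre-standardized per channel; the target is
    z-scored internally and predictions are returned in the original units.
    """

    def __init__(self, n_channels: int, seed: int = 0, lr: float = 1e-3,
                 batch_size: int = 16, epochs: int = 300, patience: int = 30,
                 val_fraction: float = 0.1, input_size: int = 7):
        self.n_channels = n_channels
        self.seed = seed
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.input_size = input_size
        self.rng = np.random.default_rng(seed)
        self.layers = self._build(self.rng)
        self.y_mean_ = 0.0
        self.y_scale_ = 1.0

    def _build(self, rng):
        layers = []
        size, cin = self.input_size, self.n_channels
        for kind, p in CNN_ARCHITECTURE:
            if kind == "conv":
                if size < p["kernel"]:
                    raise ValueError("input too small for the convolution stack")
                layers.append(_Conv(p["kernel"], cin, p["filters"], p["activation"], rng))
                size = size - p["kernel"] + 1
                cin = p["filters"]
            elif kind == "maxpool":
                layers.append(_MaxPool(p["size"], p["stride"]))
                size = (size - p["size"]) // p["stride"] + 1
            elif kind == "dropout":
                layers.append(_Dropout(p["rate"]))
            elif kind == "flatten":
                layers.append(_Flatten())
                cin = size * size * cin
                size = 1
            elif kind == "dense":
                layers.append(_Dense(cin, p["units"], p["activation"], rng))
                cin = p["units"]
        return layers

    # -- core passes -------------------------------------------------------
    def _forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training, self.rng)
        return x

    def _backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def _params(self):
        return [p for layer in self.layers for p in layer.params()]

    def _grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def _get_weights(self):
        return [p.copy() for p in self._params()]

    def _set_weights(self, weights):
        for p, w in zip(self._params(), weights):
            p[...] = w

    # -- training ----------------------------------------------------------
    def fit(self, patches: np.ndarray, y: np.ndarray) -> "CnnRegressor":
        x = np.asarray(patches, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 4 or x.shape[1] != self.input_size or x.shape[3] != self.n_channels:
            raise ValueError(f"expected (n, {self.input_size}, {self.input_size}, "
                             f"{self.n_channels}) patches, got {x.shape}")
        self.y_mean_ = float(y.mean())
        sd = float(y.std())
        self.y_scale_ = sd if sd > 0 else 1.0
        yz = (y - self.y_mean_) / self.y_scale_

        n = len(y)
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 10 else 0
        perm = self.rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        xt, yt = x[train_idx], yz[train_idx]
        xv, yv = x[val_idx], yz[val_idx]

        opt = _Adam(self._params(), lr=self.lr)
        best = (np.inf, self._get_weights())
        stale = 0
        for _ in range(self.epochs):
            order = self.rng.permutation(len(yt))
            for start in range(0, len(yt), self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = self._forward(xt[idx], training=True)[:, 0]
                dout = (2.0 / len(idx)) * (pred - yt[idx])
                self._backward(dout[:, None])
                opt.step(self._grads())
            if n_val:
                val_pred = self._forward(xv, training=False)[:, 0]
                val_mse = float(np.mean((val_pred - yv) ** 2))
                if val_mse < best[0] - 1e-6:
                    best = (val_mse, self._get_weights())
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if n_val and np.isfinite(best[0]):
            self._set_weights(best[1])
        return self

    def predict(self, patches: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = np.asarray(patches, dtype=float)
        out = np.empty(len(x))
        for start in range(0, len(x), batch_size):
            out[start:start + batch_size] = self._forward(
                x[start:start + batch_size], training=False)[:, 0]
        return out * self.y_scale_ + self.y_mean_
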