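"""Minimal NumPy layer framework with hand-written backpropagation.

Implements exactly the pieces the classifier and autoencoder need: dense and
1-D convolutional layers (same padding, arbitrary stride), batch
normalization, ReLU, global average pooling, softmax attention gates over the
channel axis (spatial) and the sequence axis (temporal), residual blocks, and
an Adam optimizer.  Every ``backward`` is verified against central finite
differences in the test suite.

Conventions: dense activations are ``[batch, features]``; convolutional
feature maps are ``[batch, channels, length]``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless unless it declares ``params``/``grads`` dicts."""

    train_mode: bool = True

    def params(self) -> dict[str, np.ndarray]:
        return getattr(self, "_params", {})

    def grads(self) -> dict[str, np.ndarray]:
        return getattr(self, "_grads", {})

    def children(self) -> list["Layer"]:
        return []

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode
        for c in self.children():
            c.set_train(mode)

    def all_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.params().items()}
        for i, c in enumerate(self.children()):
            out.update(c.all_params(f"{prefix}{i}.{type(c).__name__}."))
        return out

    def all_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.grads().items()}
        for i, c in enumerate(self.children()):
            out.update(c.all_grads(f"{prefix}{i}.{type(c).__name__}."))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / d_in)
        self._params = {"W": scale * rng.standard_normal((d_in, d_out)),
                        "b": np.zeros(d_out)}
        self._grads = {k: np.zeros_like(v) for k, v in self._params.items()}

    def forward(self, x):
        self._x = x
        return x @ self._params["W"] + self._params["b"]

    def backward(self, dy):
        self._grads["W"][...] = self._x.T @ dy
        self._grads["b"][...] = dy.sum(axis=0)
        return dy @ self._params["W"].T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv1d(Layer):
    """Same-padded 1-D convolution: output length = ceil(L / stride)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel))
        self._params = {"W": scale * rng.standard_normal((c_out, c_in * kernel)),
                        "b": np.zeros(c_out)}
        self._grads = {k: np.zeros_like(v) for k, v in self._params.items()}

    def _geometry(self, length: int) -> tuple[int, int, int]:
        l_out = -(-length // self.stride)
        pad = max((l_out - 1) * self.stride + self.kernel - length, 0)
        return l_out, pad // 2, pad - pad // 2

    def forward(self, x):
        batch, _, length = x.shape
        l_out, pl, pr = self._geometry(length)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        idx = np.arange(self.kernel)[:, None] + self.stride * np.arange(l_out)[None, :]
        cols = xp[:, :, idx].reshape(batch, self.c_in * self.kernel, l_out)
        self._cache = (x.shape, pl, cols)
        y = np.einsum("om,bml->bol", self._params["W"], cols, optimize=True)
        return y + self._params["b"][None, :, None]

    def backward(self, dy):
        (batch, _, length), pl, cols = self._cache
        self._grads["W"][...] = np.einsum("bol,bml->om", dy, cols, optimize=True)
        self._grads["b"][...] = dy.sum(axis=(0, 2))
        dcols = np.einsum("om,bol->bml", self._params["W"], dy, optimize=True)
        dcols = dcols.reshape(batch, self.c_in, self.kernel, -1)
        l_out = dcols.shape[-1]
        dxp = np.zeros((batch, self.c_in, length + pl + (self._geometry(length)[2])))
        for i in range(self.kernel):
            # output positions i, i+stride, ... are distinct, so a strided
            # slice-add accumulates correctly (no scatter needed)
            dxp[:, :, i::self.stride][:, :, :l_out] += dcols[:, :, i, :]
        return dxp[:, :, pl:pl + length]


class BatchNorm(Layer):
    """Batch normalization; axis set covers batch (and length for conv maps)."""

    def __init__(self, n_features: int, conv: bool, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.conv, self.momentum, self.eps = conv, momentum, eps
        shape = (1, n_features, 1) if conv else (1, n_features)
        self._params = {"gamma": np.ones(shape), "beta": np.zeros(shape)}
        self._grads = {k: np.zeros_like(v) for k, v in self._params.items()}
        self.running_mean = np.zeros(shape)
        self.running_var = np.ones(shape)

    @property
    def _axes(self):
        return (0, 2) if self.conv else (0,)

    def forward(self, x):
        if self.train_mode:
            mean = x.mean(axis=self._axes, keepdims=True)
            var = x.var(axis=self._axes, keepdims=True)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self._params["gamma"] * xhat + self._params["beta"]

    def backward(self, dy):
        xhat, inv = self._cache
        axes = self._axes
        m = np.prod([dy.shape[a] for a in axes])
        self._grads["gamma"][...] = (dy * xhat).sum(axis=axes, keepdims=True)
        self._grads["beta"][...] = dy.sum(axis=axes, keepdims=True)
        dxhat = dy * self._params["gamma"]
        if not self.train_mode:
            return dxhat * inv
        return (inv / m) * (m * dxhat
                            - dxhat.sum(axis=axes, keepdims=True)
                            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))


class GlobalAvgPool1d(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=2)

    def backward(self, dy):
        b, c, l = self._shape
        return np.repeat(dy[:, :, None], l, axis=2) / l


def _softmax(z: np.ndarray, axis: int) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SpatialAttention(Layer):
    """Channel gate: squeeze (GAP over length) -> bottleneck MLP -> softmax over channels.

    The scoring layer is zero-initialized so an untrained gate is exactly
    uniform (1/C per channel) — attention starts neutral and learns to
    concentrate.  Output = input * weights broadcast over length; the per-
    instance weights are simplex-valued by construction.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        hidden = max(channels // reduction, 1)
        self.fc1 = Dense(channels, hidden, rng)
        self.act = ReLU()
        self.fc2 = Dense(hidden, channels, rng, zero_init=True)
        self.last_weights: np.ndarray | None = None

    def children(self):
        return [self.fc1, self.act, self.fc2]

    def forward(self, x):
        b, c, l = x.shape
        s = x.mean(axis=2)
        a = self.fc2(self.act(self.fc1(s)))
        w = _softmax(a, axis=1)
        self._cache = (x, w, l)
        self.last_weights = w
        return x * w[:, :, None]

    def backward(self, dy):
        x, w, l = self._cache
        dx = dy * w[:, :, None]
        dw = (dy * x).sum(axis=2)
        da = w * (dw - (dw * w).sum(axis=1, keepdims=True))
        ds = self.fc1.backward(self.act.backward(self.fc2.backward(da)))
        dx += ds[:, :, None] / l
        return dx


class TemporalAttention(Layer):
    """Sequence gate: position-wise linear score -> softmax over length.

    Zero-initialized score weights give an exactly uniform untrained gate; at
    sequence length 1 the softmax weight is exactly 1.0, so the layer is the
    bit-identical identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self._params = {"v": np.zeros(channels), "b": np.zeros(1)}
        self._grads = {k: np.zeros_like(v) for k, v in self._params.items()}
        self.last_weights: np.ndarray | None = None

    def forward(self, x):
        scores = np.einsum("bcl,c->bl", x, self._params["v"]) + self._params["b"]
        w = _softmax(scores, axis=1)
        self._cache = (x, w)
        self.last_weights = w
        return x * w[:, None, :]

    def backward(self, dy):
        x, w = self._cache
        dx = dy * w[:, None, :]
        dw = (dy * x).sum(axis=1)
        de = w * (dw - (dw * w).sum(axis=1, keepdims=True))
        self._grads["v"][...] = np.einsum("bl,bcl->c", de, x)
        self._grads["b"][...] = de.sum()
        dx += de[:, None, :] * self._params["v"][None, :, None]
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN plus an identity or projected (1x1, strided) shortcut."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(c_in, c_out, kernel, stride, rng)
        self.bn1 = BatchNorm(c_out, conv=True)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, rng)
        self.bn2 = BatchNorm(c_out, conv=True)
        self.project = c_in != c_out or stride != 1
        if self.project:
            self.short_conv = Conv1d(c_in, c_out, 1, stride, rng)
            self.short_bn = BatchNorm(c_out, conv=True)
        self.relu_out = ReLU()

    def children(self):
        kids = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]
        if self.project:
            kids += [self.short_conv, self.short_bn]
        return kids

    @property
    def main_convs(self) -> list[Conv1d]:
        """The residual-path convolutions (what the 18-layer audit counts)."""
        return [self.conv1, self.conv2]

    def forward(self, x):
        f = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        s = self.short_bn(self.short_conv(x)) if self.project else x
        return self.relu_out(f + s)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dx_main = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))))
        if self.project:
            dx_short = self.short_conv.backward(self.short_bn.backward(d))
        else:
            dx_short = d
        return dx_main + dx_short


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = _softmax(logits, axis=1)
    n = len(labels)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam over a named parameter dict (as returned by ``Layer.all_params``)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x (test oracle)."""
    g = np.zeros_like(x, dtype=float)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
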