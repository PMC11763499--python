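"""Fully connected autoencoder for latent EEG feature extraction.

Encoder: 128 -> 64 -> 32 dense layers with ReLU; the 32-unit bottleneck is the
latent code used downstream.  Decoder mirrors the encoder (64 -> 128 -> input)
with a linear output layer.  Trained by Adam on mean squared reconstruction
error.  Deterministic under a fixed seed on fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix
from .nnet import Adam, Dense, ReLU, Sequential


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and training hyperparameters of the autoencoder."""

    encoder_widths: tuple[int, ...] = (128, 64, 32)
    loss: str = "mse"                     # "mse" (default), "mae", "huber"
    huber_delta: float = 1.0
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.encoder_widths or any(w < 1 for w in self.encoder_widths):
            raise ValueError("encoder widths must be positive")
        if self.loss not in ("mse", "mae", "huber"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def bottleneck(self) -> int:
        return self.encoder_widths[-1]


class Autoencoder:
    """Trained encoder/decoder pair; see :func:`train_autoencoder`."""

    def __init__(self, input_width: int, spec: AutoencoderSpec):
        self.spec = spec
        self.input_width = input_width
        rng = np.random.default_rng(spec.seed)
        enc_layers: list = []
        widths = [input_width, *spec.encoder_widths]
        for a, b in zip(widths[:-1], widths[1:]):
            enc_layers += [Dense(a, b, rng), ReLU()]
        self.encoder = Sequential(*enc_layers)
        dec_widths = [*reversed(spec.encoder_widths), input_width]
        dec_layers: list = []
        for i, (a, b) in enumerate(zip(dec_widths[:-1], dec_widths[1:])):
            dec_layers.append(Dense(a, b, rng))
            if i < len(dec_widths) - 2:
                dec_layers.append(ReLU())
        self.decoder = Sequential(*dec_layers)
        self.net = Sequential(self.encoder, self.decoder)
        self.history: list[float] = []

    def _loss_grad(self, xhat: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
        r = xhat - x
        n = r.size
        if self.spec.loss == "mse":
            return float(np.mean(r**2)), 2.0 * r / n
        if self.spec.loss == "mae":
            return float(np.mean(np.abs(r))), np.sign(r) / n
        d = self.spec.huber_delta
        quad = np.abs(r) <= d
        loss = np.where(quad, 0.5 * r**2, d * (np.abs(r) - 0.5 * d))
        grad = np.where(quad, r, d * np.sign(r))
        return float(loss.mean()), grad / n

    def reconstruction_loss(self, x: np.ndarray) -> float:
        return self._loss_grad(self.net(np.asarray(x, dtype=float)), x)[0]

    def reconstruction_mse(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(np.mean((self.net(x) - x) ** 2))

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder(np.asarray(x, dtype=float))


def train_autoencoder(x: np.ndarray, spec: AutoencoderSpec) -> Autoencoder:
    """Fit the autoencoder on instance rows ``x`` [n x width].

    After a positive training budget, the final training reconstruction loss
    must be below the loss at initialization (asserted); with zero epochs the
    returned model equals its initialization.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("training input must be [n_instances x width]")
    if not np.all(np.isfinite(x)):
        raise ValueError("training input contains non-finite values")
    model = Autoencoder(x.shape[1], spec)
    initial = model.reconstruction_loss(x)
    model.history.append(initial)
    if spec.epochs == 0:
        return model
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model.net.all_params(), lr=spec.learning_rate)
    n = len(x)
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            xb = x[order[start:start + spec.batch_size]]
            xhat = model.net(xb)
            _, grad = model._loss_grad(xhat, xb)
            model.net.backward(grad)
            opt.step(model.net.all_grads())
        model.history.append(model.reconstruction_loss(x))
    if model.history[-1] >= initial:
        raise RuntimeError(
            f"autoencoder failed to improve: initial {initial:.4g}, "
            f"final {model.history[-1]:.4g}")
    return model


def encode(model: Autoencoder, instances: np.ndarray,
           labels: np.ndarray) -> FeatureMatrix:
    """Latent features: exactly ``spec.bottleneck`` columns tagged ``latent``."""
    instances = np.asarray(instances, dtype=float)
    if instances.shape[1] != model.input_width:
        raise ValueError(
            f"instance width {instances.shape[1]} != training width {model.input_width}")
    z = model.encode(instances)
    width = model.spec.bottleneck
    names = [f"latent_{i}" for i in range(width)]
    return FeatureMatrix(z, names, ["latent"] * width, np.asarray(labels, dtype=int))
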