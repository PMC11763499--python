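"""1-D residual network with a double (spatial + temporal) attention mechanism.

The default architecture carries 18 convolutional layers inside residual
blocks: 9 basic blocks (two convolutions each) arranged in 4 stages of
2/2/3/2 blocks.  Kernel sizes are assigned per stage from {7, 5, 3, 3} — wide
kernels early for long-range structure, narrow ones late — with stride-2
downsampling at each stage transition and same padding elsewhere, batch
normalization and ReLU throughout, 1x1 projection shortcuts where shapes
change, and a global-average-pooling head onto 2 output classes.

After every stage a double attention gate is applied: a spatial gate
(softmax over learned convolutional channels; in raw-epoch mode, over EEG
channels at the input) and a temporal gate (softmax over sequence positions).
Both start exactly uniform and are learned end-to-end.

In feature mode the selected feature vector of length D is presented as a
1 x D sequence, so the temporal gate weights individual features and the
spatial gate weights learned filter channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .nnet import (
    Adam,
    Dense,
    GlobalAvgPool1d,
    Layer,
    ResidualBlock,
    Sequential,
    SpatialAttention,
    TemporalAttention,
    _softmax,
    softmax_cross_entropy,
)

ALLOWED_KERNELS = (3, 5, 7)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture + training hyperparameters of the attention ResNet."""

    blocks_per_stage: tuple[int, ...] = (2, 2, 3, 2)
    stage_kernels: tuple[int, ...] = (7, 5, 3, 3)
    stage_channels: tuple[int, ...] = (16, 32, 64, 128)
    spatial_attention: bool = True
    temporal_attention: bool = True
    input_spatial_attention: bool = False   # gate EEG channels directly (raw-epoch mode)
    n_classes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.blocks_per_stage) == len(self.stage_kernels)
                == len(self.stage_channels)):
            raise ValueError("stage plan lists must have equal length")
        for s, k in enumerate(self.stage_kernels):
            if k not in ALLOWED_KERNELS:
                raise ValueError(f"stage {s}: kernel {k} not in {ALLOWED_KERNELS}")
        if any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("each stage needs at least one block")
        if self.n_classes != 2:
            raise ValueError("binary classifier: n_classes must be 2")

    @property
    def n_conv_layers(self) -> int:
        """Convolutions on residual main paths (2 per basic block)."""
        return 2 * sum(self.blocks_per_stage)


#: Reduced plan for quick end-to-end runs: 4 blocks (8 residual convolutions).
REDUCED_CONFIG = ModelConfig(
    blocks_per_stage=(2, 2), stage_kernels=(7, 5), stage_channels=(16, 32), epochs=20
)


class AttentionResNet(Layer):
    """The network graph; build via :func:`build_model`."""

    def __init__(self, cfg: ModelConfig, input_width: int, input_channels: int = 1):
        self.cfg = cfg
        self.input_width = input_width
        self.input_channels = input_channels
        rng = np.random.default_rng(cfg.seed)
        layers: list[Layer] = []
        c_in = input_channels
        width = input_width
        if cfg.input_spatial_attention:
            layers.append(SpatialAttention(c_in, rng))
        for stage, (n_blocks, kernel, c_out) in enumerate(
                zip(cfg.blocks_per_stage, cfg.stage_kernels, cfg.stage_channels)):
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage > 0) else 1
                layers.append(ResidualBlock(c_in, c_out, kernel, stride, rng))
                c_in = c_out
                width = -(-width // stride)
                if width < 1:
                    raise ValueError(
                        f"stage {stage}: sequence width shrinks below 1")
            if cfg.spatial_attention:
                layers.append(SpatialAttention(c_out, rng))
            if cfg.temporal_attention:
                layers.append(TemporalAttention(c_out, rng))
        layers.append(GlobalAvgPool1d())
        self.body = Sequential(*layers)
        self.head = Dense(c_in, cfg.n_classes, rng)
        self.net = Sequential(self.body, self.head)

    def children(self):
        return [self.net]

    def forward(self, x):
        return self.net(x)

    def backward(self, dy):
        return self.net.backward(dy)

    # -- introspection -----------------------------------------------------
    def residual_blocks(self) -> list[ResidualBlock]:
        return [l for l in self.body.layers if isinstance(l, ResidualBlock)]

    def count_block_convs(self) -> int:
        """Audit: convolutional layers on residual main paths."""
        return sum(len(b.main_convs) for b in self.residual_blocks())

    def attention_layers(self) -> list[Layer]:
        return [l for l in self.body.layers
                if isinstance(l, (SpatialAttention, TemporalAttention))]


def build_model(cfg: ModelConfig, input_width: int,
                input_channels: int = 1) -> AttentionResNet:
    """Construct an untrained network for inputs of ``input_width`` positions.

    ``input_channels`` is 1 in feature mode (vector reshaped to a 1 x D
    sequence) and the EEG channel count in raw-epoch mode.
    """
    if input_width < 8:
        raise ValueError("input_width must be >= 8 (reshaping contract)")
    return AttentionResNet(cfg, input_width, input_channels)


@dataclass
class TrainedModel:
    """Fitted network plus its config echo and training history."""

    network: AttentionResNet
    config: ModelConfig
    input_width: int
    input_channels: int
    history: list[float] = field(default_factory=list)

    def _to_maps(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:                      # feature mode: [n, D] -> [n, 1, D]
            x = x[:, None, :]
        if x.shape[2] != self.input_width or x.shape[1] != self.input_channels:
            raise ValueError(
                f"input shape {x.shape[1:]} != trained shape "
                f"({self.input_channels}, {self.input_width})")
        return x


def train(features: FeatureMatrix | np.ndarray, labels: np.ndarray | None,
          cfg: ModelConfig, input_channels: int = 1) -> TrainedModel:
    """Train by mini-batch Adam on softmax cross-entropy.

    Accepts a :class:`FeatureMatrix` (labels implied) or a raw array plus
    labels.  Deterministic under ``cfg.seed`` on fixed data.  Divergence
    (non-finite loss) aborts with a diagnostic rather than returning a
    silently broken model.
    """
    if isinstance(features, FeatureMatrix):
        x, y = features.values, features.labels
    else:
        x, y = np.asarray(features, dtype=float), np.asarray(labels, dtype=int)
    if x.ndim == 2:
        maps = x[:, None, :]
    else:
        maps = x
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    net = build_model(cfg, maps.shape[2], maps.shape[1])
    model = TrainedModel(net, cfg, maps.shape[2], maps.shape[1])
    if cfg.epochs == 0:
        net.set_train(False)
        return model
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(net.all_params(), lr=cfg.learning_rate)
    n = len(y)
    net.set_train(True)
    for ep in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            if len(sel) < 2:                 # batch norm needs batch statistics
                continue
            logits = net(maps[sel])
            loss, grad = softmax_cross_entropy(logits, y[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {ep}: loss {loss}")
            net.backward(grad)
            opt.step(net.all_grads())
            ep_loss += loss
            n_batches += 1
        model.history.append(ep_loss / max(n_batches, 1))
    net.set_train(False)
    return model


def predict(model: TrainedModel, features: FeatureMatrix | np.ndarray,
            batch_size: int = 1024) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels.

    Probabilities are softmax outputs (rows sum to 1); the hard label is 1
    only when P(class 1) strictly exceeds 0.5, so an exact tie yields class 0.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    maps = model._to_maps(x)
    model.network.set_train(False)
    probs = []
    for start in range(0, len(maps), batch_size):
        logits = model.network(maps[start:start + batch_size])
        probs.append(_softmax(logits, axis=1))
    p = np.vstack(probs) if probs else np.empty((0, 2))
    labels = (p[:, 1] > 0.5).astype(int)
    return p, labels
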