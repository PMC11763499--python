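"""Epoching and the unified feature vector: autoencoder latents + time + frequency.

Each classification instance is a window of multichannel EEG.  ``window=1``
reproduces the row-wise source layout (one instance per time sample); larger
windows enable spectral descriptors.  Per instance the unified vector is

    [32 autoencoder latents] ++ [mean/variance/skewness per channel]
                             ++ [theta/alpha/beta/gamma band power + spectral
                                entropy per channel]    (windows >= 8 only)

followed by per-feature z-scoring with parameters fitted on the training split
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy import signal

from .synth import Recording

#: Spectral bands available inside the 4-40 Hz analysis passband.
FEATURE_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}

#: Minimum window (samples) for spectral features to be defined.
MIN_SPECTRAL_WINDOW = 8


@dataclass
class EpochSet:
    """Windowed instances: ``epochs`` is [n_instances x n_channels x window]."""

    epochs: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    window: int
    step: int
    sfreq: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be [n_instances x n_channels x window]")
        if len(self.labels) != len(self.epochs):
            raise ValueError("labels must align with epochs")

    @property
    def n_instances(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def subset(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(self.epochs[idx], self.labels[idx], self.channel_names,
                        self.window, self.step, self.sfreq)

    def flattened(self) -> np.ndarray:
        """[n_instances x (n_channels * window)] view for vector models."""
        return self.epochs.reshape(self.n_instances, -1)


@dataclass
class FeatureMatrix:
    """Per-instance feature vectors with provenance-tagged names."""

    values: np.ndarray
    feature_names: list[str]
    tags: list[str]                      # one of {"latent", "time", "freq"} per feature
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names) or len(self.feature_names) != len(self.tags):
            raise ValueError("feature_names/tags must match value columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.labels) != len(self.values):
            raise ValueError("labels must align with rows")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values[idx], list(self.feature_names),
                             list(self.tags), self.labels[idx])

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            self.values[:, mask],
            [n for n, m in zip(self.feature_names, mask) if m],
            [t for t, m in zip(self.tags, mask) if m],
            self.labels,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)
        sidecar = Path(str(path) + ".meta.json")
        sidecar.write_text(json.dumps({"tags": self.tags}, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=int)
        sidecar = Path(str(path) + ".meta.json")
        tags = (json.loads(sidecar.read_text())["tags"] if sidecar.exists()
                else ["time"] * df.shape[1])
        return cls(df.to_numpy(dtype=float), list(df.columns), tags, labels)


def epoch(rec: Recording, window: int, step: int) -> EpochSet:
    """Slice a recording into windows: floor((n - window)/step) + 1 instances."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > rec.n_samples:
        raise ValueError(f"window={window} exceeds recording length {rec.n_samples}")
    n = (rec.n_samples - window) // step + 1
    idx = np.arange(window)[None, :] + step * np.arange(n)[:, None]
    epochs = rec.data[:, idx].transpose(1, 0, 2)        # [n x channels x window]
    label = rec.label if rec.label is not None else 0
    return EpochSet(epochs, np.full(n, label), rec.channel_names, window, step, rec.sfreq)


def concat_epoch_sets(sets: Sequence[EpochSet]) -> EpochSet:
    first = sets[0]
    for es in sets[1:]:
        if (es.channel_names, es.window, es.step, es.sfreq) != (
                first.channel_names, first.window, first.step, first.sfreq):
            raise ValueError("epoch sets have incompatible geometry")
    return EpochSet(np.concatenate([es.epochs for es in sets]),
                    np.concatenate([es.labels for es in sets]),
                    first.channel_names, first.window, first.step, first.sfreq)


def time_domain_features(es: EpochSet) -> FeatureMatrix:
    """Per-channel mean, variance, skewness (population moments).

    Skewness of a zero-variance window (including any window < 3 samples) is
    defined as 0 to keep the matrix finite in the row-wise layout.
    """
    x = es.epochs
    mean = x.mean(axis=2)
    var = x.var(axis=2)
    if es.window >= 3:
        centered = x - mean[:, :, None]
        m3 = (centered**3).mean(axis=2)
        denom = np.where(var > 0, var, 1.0) ** 1.5
        skew = np.where(var > 0, m3 / denom, 0.0)
    else:
        skew = np.zeros_like(var)
    names, tags, cols = [], [], []
    for stat, block in (("mean", mean), ("variance", var), ("skewness", skew)):
        for c, ch in enumerate(es.channel_names):
            names.append(f"{stat}_{ch}")
            tags.append("time")
            cols.append(block[:, c])
    return FeatureMatrix(np.column_stack(cols), names, tags, es.labels.copy())


def frequency_domain_features(es: EpochSet) -> FeatureMatrix | None:
    """Band powers (theta/alpha/beta/gamma) + spectral entropy per channel.

    Returns ``None`` for windows below 8 samples, where the periodogram grid
    cannot resolve the bands.  Spectral entropy is the Shannon entropy (bits)
    of the periodogram normalized over the 4-40 Hz analysis band; a zero-power
    window gets entropy 0.
    """
    if es.window < MIN_SPECTRAL_WINDOW:
        return None
    freqs, pxx = signal.periodogram(es.epochs, fs=es.sfreq, axis=2, detrend=False)
    in_band = (freqs >= 4.0) & (freqs <= 40.0)
    names, tags, cols = [], [], []
    for band, (lo, hi) in FEATURE_BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        bp = pxx[:, :, sel].sum(axis=2)
        for c, ch in enumerate(es.channel_names):
            names.append(f"bp_{band}_{ch}")
            tags.append("freq")
            cols.append(bp[:, c])
    p = pxx[:, :, in_band]
    tot = p.sum(axis=2, keepdims=True)
    q = p / np.where(tot > 0, tot, 1.0)
    logq = np.log2(np.where(q > 0, q, 1.0))
    ent = -(q * logq).sum(axis=2)
    for c, ch in enumerate(es.channel_names):
        names.append(f"spectral_entropy_{ch}")
        tags.append("freq")
        cols.append(ent[:, c])
    return FeatureMatrix(np.column_stack(cols), names, tags, es.labels.copy())


def concat_features(*blocks: FeatureMatrix | None) -> FeatureMatrix:
    """Concatenate feature blocks column-wise; labels must agree across blocks."""
    present = [b for b in blocks if b is not None]
    if not present:
        raise ValueError("no feature blocks given")
    first = present[0]
    for b in present[1:]:
        if b.n_instances != first.n_instances or not np.array_equal(b.labels, first.labels):
            raise ValueError("feature blocks have mismatched instances or labels")
    return FeatureMatrix(
        np.hstack([b.values for b in present]),
        [n for b in present for n in b.feature_names],
        [t for b in present for t in b.tags],
        first.labels.copy(),
    )


@dataclass
class Standardizer:
    """Per-feature z-scoring with parameters frozen on the training split."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, fm: FeatureMatrix) -> "Standardizer":
        mean = fm.values.mean(axis=0)
        scale = fm.values.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)          # constant features pass through
        return cls(mean, scale)

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        return FeatureMatrix((fm.values - self.mean) / self.scale,
                             list(fm.feature_names), list(fm.tags), fm.labels.copy())
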