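"""Seeded two-class synthetic EEG generation.

Emulates a 19-channel, 128 Hz scalp EEG acquisition in the 10-20 montage with a
controllable class contrast: each class mixes band-limited Gaussian noise in the
canonical delta/theta/alpha/beta/gamma bands with configurable relative power,
plus white sensor noise.  The default contrast follows the classical ADHD
electrophysiology picture — elevated theta and reduced beta power in the
ADHD class relative to controls.

Artifacts (eye blinks with a frontally-dominant scalp topography, mains line
noise) are injected by a separate pure function so that artifact-free ground
truth remains available for validating the cleaning stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

#: 10-20 channel order used throughout (frontal → posterior naming of the source data).
CHANNELS_1020: tuple[str, ...] = (
    "Fz", "Cz", "Pz", "C3", "T3", "C4", "T4", "Fp1", "Fp2", "F3",
    "F4", "F7", "F8", "P3", "P4", "T5", "T6", "O1", "O2",
)

#: Canonical EEG band edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Blink scalp topography: dominant on the periocular channels, decaying toward
#: the back of the head (blinks volume-conduct across the scalp).
BLINK_TOPOGRAPHY: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0,
    "F3": 0.4, "F4": 0.4, "F7": 0.4, "F8": 0.4, "Fz": 0.4,
    "C3": 0.15, "C4": 0.15, "Cz": 0.15, "T3": 0.15, "T4": 0.15,
    "P3": 0.05, "P4": 0.05, "Pz": 0.05, "T5": 0.05, "T6": 0.05,
    "O1": 0.05, "O2": 0.05,
}

#: Default per-class relative band power.  Control: broadband background with a
#: posterior-style alpha emphasis.  ADHD: theta elevated 3x, beta halved — the
#: direction of the classical theta/beta-ratio finding.
DEFAULT_CLASS_BAND_POWER: tuple[dict[str, float], dict[str, float]] = (
    {"delta": 1.0, "theta": 1.0, "alpha": 1.2, "beta": 1.0, "gamma": 0.4},
    {"delta": 1.0, "theta": 3.0, "alpha": 1.2, "beta": 0.5, "gamma": 0.4},
)


class ConfigurationError(ValueError):
    """Raised when a generator/filter configuration is invalid."""


class ParseError(ValueError):
    """Raised when a dataset file fails validation; message names row/column."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    Amplitudes are in microvolts; ``class_band_power`` maps each class label to
    relative band powers (per-band variance share before the global amplitude
    scale is applied).
    """

    n_channels: int = 19
    channel_names: tuple[str, ...] = CHANNELS_1020
    sfreq: float = 128.0
    n_samples_per_class: int = 12800
    class_band_power: tuple[Mapping[str, float], Mapping[str, float]] = DEFAULT_CLASS_BAND_POWER
    amplitude_uv: float = 10.0
    noise_sd: float = 1.0
    artifact_rate_blinks: float = 5.0      # events per minute
    blink_amplitude_uv: float = 120.0
    blink_duration_s: float = 0.3
    line_noise_hz: float = 50.0
    line_noise_amplitude_uv: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels != len(self.channel_names):
            raise ConfigurationError(
                f"n_channels={self.n_channels} != len(channel_names)={len(self.channel_names)}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        if self.sfreq <= 0:
            raise ConfigurationError("sfreq must be positive")
        if self.n_samples_per_class < 0:
            raise ConfigurationError("n_samples_per_class must be >= 0")
        for cls_powers in self.class_band_power:
            for band, p in cls_powers.items():
                if band not in BANDS:
                    raise ConfigurationError(f"unknown band {band!r}")
                if p < 0:
                    raise ConfigurationError(f"band power for {band!r} must be >= 0")
        if self.noise_sd < 0 or self.amplitude_uv < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if self.artifact_rate_blinks < 0:
            raise ConfigurationError("artifact_rate_blinks must be >= 0")
        if not 0 < self.line_noise_hz < self.sfreq / 2:
            raise ConfigurationError("line_noise_hz must lie below Nyquist")


@dataclass
class Recording:
    """A multichannel voltage time series: ``data`` is [n_channels x n_samples] in uV."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    sfreq: float
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [channels x samples]")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("row count must match number of channel names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0, 1 or None")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.channel_names, self.sfreq, self.label)


@dataclass
class LabeledDataset:
    """Row-wise instance table: one row per instance, one column per channel, plus labels."""

    rows: pd.DataFrame
    labels: np.ndarray
    sfreq: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.rows):
            raise ValueError("labels length must equal number of rows")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    @property
    def n_instances(self) -> int:
        return len(self.rows)


def _band_limited_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                        lo: float, hi: float, sfreq: float) -> np.ndarray:
    """Unit-variance (per channel) Gaussian noise band-limited to [lo, hi] Hz."""
    white = rng.standard_normal((n_channels, n_samples))
    nyq = sfreq / 2
    hi = min(hi, nyq * 0.99)
    sos = signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = signal.sosfiltfilt(sos, white, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_recording(config: SynthConfig, class_label: int) -> Recording:
    """Generate one continuous recording for a class.

    The signal is a sum over canonical bands of band-limited Gaussian noise,
    scaled so the per-band variance share matches ``class_band_power`` for that
    class, plus white sensor noise.  Deterministic under ``config.seed`` (the
    class label participates in the stream derivation so the two classes use
    independent draws).
    """
    if class_label not in (0, 1):
        raise ConfigurationError("class_label must be 0 or 1")
    n = config.n_samples_per_class
    rng = np.random.default_rng((config.seed, class_label))
    if n == 0:
        return Recording(np.empty((config.n_channels, 0)), config.channel_names,
                         config.sfreq, class_label)
    if n < 64:
        raise ConfigurationError("need at least 64 samples for band-limited synthesis")
    powers = dict(config.class_band_power[class_label])
    total = sum(powers.values())
    if total <= 0:
        raise ConfigurationError("class band powers must not all be zero")
    data = np.zeros((config.n_channels, n))
    for band, (lo, hi) in BANDS.items():
        p = powers.get(band, 0.0)
        if p <= 0:
            continue
        comp = _band_limited_noise(rng, config.n_channels, n, lo, hi, config.sfreq)
        data += np.sqrt(p / total) * comp
    data *= config.amplitude_uv
    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)
    return Recording(data, config.channel_names, config.sfreq, class_label)


def _blink_kernel(sfreq: float, duration_s: float) -> np.ndarray:
    """Smooth positive bump: squared-cosine (Hann) window of the blink duration."""
    n = max(int(round(duration_s * sfreq)), 3)
    t = np.arange(n)
    return np.sin(np.pi * t / (n - 1)) ** 2


def inject_artifacts(rec: Recording, config: SynthConfig) -> Recording:
    """Return a copy of ``rec`` with eye blinks and mains line noise added.

    Blinks are Hann-shaped transients of ``blink_duration_s`` placed at
    uniformly random onsets at ``artifact_rate_blinks`` events/min, projected
    through the frontally-dominant :data:`BLINK_TOPOGRAPHY`.  Line noise is a
    sinusoid at ``line_noise_hz`` with a random phase per channel.  The input
    recording is not modified.
    """
    if rec.n_samples == 0:
        raise ConfigurationError("cannot inject artifacts into an empty recording")
    for ch in ("Fp1", "Fp2"):
        if ch not in rec.channel_names:
            raise ConfigurationError(f"frontal channel {ch!r} missing from recording")
    out = rec.copy()
    rng = np.random.default_rng((config.seed, 2, rec.label if rec.label is not None else 0))
    topo = np.array([BLINK_TOPOGRAPHY.get(ch, 0.05) for ch in rec.channel_names])

    n_blinks = int(round(config.artifact_rate_blinks * rec.duration_s / 60.0))
    if n_blinks > 0 and config.blink_amplitude_uv > 0:
        kernel = _blink_kernel(rec.sfreq, config.blink_duration_s)
        klen = len(kernel)
        if klen < rec.n_samples:
            onsets = rng.integers(0, rec.n_samples - klen, size=n_blinks)
            trace = np.zeros(rec.n_samples)
            for onset in onsets:
                trace[onset:onset + klen] += kernel
            out.data += config.blink_amplitude_uv * topo[:, None] * trace[None, :]

    if config.line_noise_amplitude_uv > 0:
        t = np.arange(rec.n_samples) / rec.sfreq
        phases = rng.uniform(0, 2 * np.pi, size=rec.n_channels)
        out.data += config.line_noise_amplitude_uv * np.sin(
            2 * np.pi * config.line_noise_hz * t[None, :] + phases[:, None]
        )
    return out


def blink_trace(rec: Recording, config: SynthConfig) -> np.ndarray:
    """The blink time-course that :func:`inject_artifacts` adds (unit amplitude).

    Replays the same seeded draws; useful as ground truth when validating
    artifact rejection.
    """
    rng = np.random.default_rng((config.seed, 2, rec.label if rec.label is not None else 0))
    kernel = _blink_kernel(rec.sfreq, config.blink_duration_s)
    klen = len(kernel)
    n_blinks = int(round(config.artifact_rate_blinks * rec.duration_s / 60.0))
    trace = np.zeros(rec.n_samples)
    if n_blinks > 0 and klen < rec.n_samples:
        onsets = rng.integers(0, rec.n_samples - klen, size=n_blinks)
        for onset in onsets:
            trace[onset:onset + klen] += kernel
    return trace


# ---------------------------------------------------------------------------
# Tabular (row-wise) dataset I/O
# ---------------------------------------------------------------------------

def recordings_to_dataset(recordings: Sequence[Recording]) -> LabeledDataset:
    """Stack recordings row-wise (one instance per time sample, the source layout)."""
    if not recordings:
        raise ValueError("need at least one recording")
    names = recordings[0].channel_names
    sfreq = recordings[0].sfreq
    blocks, labels = [], []
    for rec in recordings:
        if rec.channel_names != names:
            raise ValueError("recordings have mismatched channel names")
        if rec.label is None:
            raise ValueError("recordings must be labeled")
        blocks.append(rec.data.T)
        labels.append(np.full(rec.n_samples, rec.label))
    rows = pd.DataFrame(np.vstack(blocks), columns=list(names))
    return LabeledDataset(rows, np.concatenate(labels), sfreq, names)


def write_dataset_csv(ds: LabeledDataset, path: str | Path) -> None:
    """Write the row-wise layout: header of channel names then ``label``; gzip by suffix."""
    df = ds.rows.copy()
    df["label"] = ds.labels
    df.to_csv(path, index=False)


def write_dataset_csv_split(ds: LabeledDataset, signals_path: str | Path,
                            labels_path: str | Path) -> None:
    """Two-file layout: signal rows in one CSV, class labels saved separately."""
    ds.rows.to_csv(signals_path, index=False)
    pd.DataFrame({"label": ds.labels}).to_csv(labels_path, index=False)


def read_dataset_csv(path: str | Path, sfreq: float = 128.0) -> LabeledDataset:
    """Read and validate the row-wise CSV layout written by :func:`write_dataset_csv`."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ParseError(f"malformed CSV {path}: {exc}") from exc
    if df.columns.size < 2 or df.columns[-1] != "label":
        raise ParseError(f"{path}: last column must be 'label', got {list(df.columns)[-3:]}")
    channel_cols = list(df.columns[:-1])
    for col in channel_cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(np.argmax(df[col].isna().to_numpy() | bad.to_numpy()))
            raise ParseError(f"{path}: non-numeric or missing value at row {row}, column {col!r}")
    labels = df["label"].to_numpy()
    valid = np.isin(labels, (0, 1))
    if not valid.all():
        row = int(np.argmax(~valid))
        raise ParseError(f"{path}: label outside {{0,1}} at row {row}")
    return LabeledDataset(df[channel_cols].astype(float), labels.astype(int),
                          sfreq, tuple(channel_cols))
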