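"""Recording cleanup: 4-40 Hz bandpass, ICA artifact rejection, PSD/SNR checks.

The filter is a zero-phase forward-backward Butterworth (order 4, effective 8)
applied as second-order sections; ICA is FastICA (fixed-point, deflation) with
a fixed seed so the decomposition is reproducible.  Because no human reviewer
is in the loop, artifact components are flagged automatically by two criteria:
correlation with a frontal blink surrogate (mean of Fp1/Fp2 low-passed at
4 Hz) and excess kurtosis, both thresholds configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA

from .synth import ConfigurationError, Recording


@dataclass
class ICADecomposition:
    """FastICA factorization of a recording.

    ``unmixing`` is [k x n_channels] applied to the mean-centered data,
    ``mixing`` its pseudo-inverse [n_channels x k]; ``sources`` [k x n_samples].
    With k == n_channels, ``mixing @ sources + mean`` reconstructs the input to
    numerical tolerance; with k < n_channels it is the rank-k (PCA-whitened)
    approximation.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray
    mean: np.ndarray
    channel_names: tuple[str, ...]
    sfreq: float
    artifact_scores: dict[str, np.ndarray] | None = None

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Back-project sources to channel space, optionally zeroing components."""
        src = self.sources if keep is None else self.sources * np.asarray(keep)[:, None]
        return self.mixing @ src + self.mean[:, None]


@dataclass
class PSDResult:
    """Welch power spectral density per channel (uV^2/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray                   # [n_channels x n_freqs]
    channel_names: tuple[str, ...]
    window_s: float
    overlap: float


def bandpass(rec: Recording, lo: float = 4.0, hi: float = 40.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass; returns a new recording of identical shape."""
    nyq = rec.sfreq / 2
    if not 0 < lo < hi:
        raise ConfigurationError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ConfigurationError(f"hi={hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return out


def compute_psd(rec: Recording, window_s: float = 2.0, overlap: float = 0.5) -> PSDResult:
    """Welch-averaged periodogram per channel.

    Uses Hann windows of ``window_s`` seconds with fractional ``overlap``; the
    integral of the density over frequency approximates the signal variance
    (Parseval, up to windowing loss).
    """
    nperseg = int(round(window_s * rec.sfreq))
    if nperseg < 2 or nperseg > rec.n_samples:
        raise ConfigurationError(
            f"window of {nperseg} samples does not fit recording of {rec.n_samples}")
    if not 0 <= overlap < 1:
        raise ConfigurationError("overlap must be in [0, 1)")
    freqs, power = signal.welch(
        rec.data, fs=rec.sfreq, nperseg=nperseg,
        noverlap=int(nperseg * overlap), axis=1, detrend=False,
    )
    return PSDResult(freqs, power, rec.channel_names, window_s, overlap)


def run_ica(rec: Recording, k: int | None = None, seed: int = 0,
            max_iter: int = 1000, tol: float = 1e-4) -> ICADecomposition:
    """FastICA decomposition of a recording into k independent components."""
    k = rec.n_channels if k is None else k
    if k < 1 or k > rec.n_channels:
        raise ConfigurationError(f"k={k} must be in [1, n_channels={rec.n_channels}]")
    if rec.n_samples < 10 * rec.n_channels:
        raise ConfigurationError(
            f"recording too short for ICA: need >= {10 * rec.n_channels} samples")
    # rank check: ICA on rank-deficient data is ill-posed
    if np.linalg.matrix_rank(rec.data - rec.data.mean(axis=1, keepdims=True)) < k:
        raise ConfigurationError(
            "input is rank-deficient for the requested k; try fewer components")
    ica = FastICA(n_components=k, algorithm="deflation", whiten="unit-variance",
                  max_iter=max_iter, tol=tol, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(rec.data.T).T       # [k x n_samples]
    return ICADecomposition(
        unmixing=ica.components_,
        mixing=ica.mixing_,
        sources=sources,
        mean=ica.mean_,
        channel_names=rec.channel_names,
        sfreq=rec.sfreq,
    )


def score_components(dec: ICADecomposition, rec: Recording,
                     blink_corr_threshold: float = 0.6,
                     kurtosis_threshold: float = 10.0) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Flag artifact components automatically.

    A component is flagged when |corr| with the frontal blink surrogate (mean
    of Fp1/Fp2 low-passed at 4 Hz) reaches ``blink_corr_threshold``, or its
    excess kurtosis exceeds ``kurtosis_threshold`` (blinks are sparse, spiky
    sources; ongoing EEG is near-Gaussian).
    """
    for ch in ("Fp1", "Fp2"):
        if ch not in rec.channel_names:
            raise ConfigurationError(f"frontal channel {ch!r} required for blink surrogate")
    idx = [rec.channel_names.index(ch) for ch in ("Fp1", "Fp2")]
    frontal = rec.data[idx].mean(axis=0)
    nyq = rec.sfreq / 2
    sos = signal.butter(4, 4.0 / nyq, btype="lowpass", output="sos")
    surrogate = signal.sosfiltfilt(sos, frontal)

    k = dec.n_components
    corr = np.zeros(k)
    s_sd = surrogate.std()
    for j in range(k):
        src = dec.sources[j]
        if src.std() == 0 or s_sd == 0:
            corr[j] = 0.0
        else:
            corr[j] = np.corrcoef(src, surrogate)[0, 1]
    kurt = stats.kurtosis(dec.sources, axis=1, fisher=True)
    flags = (np.abs(corr) >= blink_corr_threshold) | (kurt > kurtosis_threshold)
    scores = {"blink_corr": corr, "kurtosis": kurt}
    return flags, scores


def reject_components(dec: ICADecomposition, rec: Recording,
                      blink_corr_threshold: float = 0.6,
                      kurtosis_threshold: float = 10.0,
                      flags: np.ndarray | None = None) -> Recording:
    """Reconstruct the recording with flagged artifact components zeroed.

    ``flags`` overrides the automatic criteria when given.  Refuses to zero
    every component (that would return an empty signal).
    """
    if flags is None:
        flags, scores = score_components(dec, rec, blink_corr_threshold, kurtosis_threshold)
        dec.artifact_scores = scores
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (dec.n_components,):
        raise ValueError("flags must have one entry per component")
    if flags.all():
        raise ConfigurationError(
            "criteria flag every component; refusing to return an empty signal")
    out = rec.copy()
    out.data = dec.reconstruct(keep=~flags)
    return out


def compute_snr(clean_reference: Recording, observed: Recording) -> np.ndarray:
    """Per-channel SNR in dB: 10*log10(power(reference) / power(observed - reference)).

    Channels where the residual is exactly zero return ``+inf`` (the sentinel
    for a perfect match).
    """
    if clean_reference.data.shape != observed.data.shape:
        raise ValueError("recordings must have equal shapes")
    ref = clean_reference.data
    resid = observed.data - ref
    p_ref = np.mean(ref**2, axis=1)
    p_res = np.mean(resid**2, axis=1)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(np.where(p_res > 0, p_ref / p_res, np.inf))
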