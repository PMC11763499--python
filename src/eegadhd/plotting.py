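"""Basic PSD and ROC figures (matplotlib is imported lazily)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import PSDResult


def plot_psd(psd: PSDResult, path: str | Path, title: str = "Power spectral density") -> None:
    """One line per channel, log power over frequency."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for c, name in enumerate(psd.channel_names):
        ax.semilogy(psd.frequencies, psd.power[c], lw=0.7, label=name)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (uV^2/Hz)")
    ax.set_title(title)
    if len(psd.channel_names) <= 6:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(points: np.ndarray, auc: float, path: str | Path,
             label: str = "model") -> None:
    """ROC curve with the chance diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(points[:, 0], points[:, 1], label=f"{label} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
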