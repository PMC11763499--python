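"""Shared fixtures: small seeded recordings and toy feature problems."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegadhd.synth import SynthConfig, generate_recording, inject_artifacts

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    """60 s, two-class config with default band-power contrast."""
    return SynthConfig(n_samples_per_class=128 * 60, seed=7)


@pytest.fixture(scope="session")
def rec_control(synth_cfg):
    return generate_recording(synth_cfg, 0)


@pytest.fixture(scope="session")
def rec_adhd(synth_cfg):
    return generate_recording(synth_cfg, 1)


@pytest.fixture(scope="session")
def rec_artifacted(rec_control, synth_cfg):
    return inject_artifacts(rec_control, synth_cfg)


def planted_features(n: int, d: int, informative: int, shift: float, seed: int):
    """Two balanced Gaussian classes; the first `informative` features carry a
    mean shift of `shift` standard deviations."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.standard_normal((n, d))
    x[y == 1, :informative] += shift
    return x, y
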