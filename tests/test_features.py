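"""Epoching arithmetic, moment/spectral feature oracles, autoencoder training."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from eegadhd.autoencoder import AutoencoderSpec, encode, train_autoencoder
from eegadhd.features import (
    EpochSet,
    Standardizer,
    concat_features,
    epoch,
    frequency_domain_features,
    time_domain_features,
)
from eegadhd.synth import Recording


def make_epochset(epochs, sfreq=128.0, labels=None):
    epochs = np.asarray(epochs, dtype=float)
    n, c, w = epochs.shape
    labels = np.zeros(n, dtype=int) if labels is None else labels
    return EpochSet(epochs, labels, tuple(f"c{i}" for i in range(c)), w, w, sfreq)


class TestEpoch:
    def test_row_mode_instance_count(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.standard_normal((19, 50_000)),
                        tuple(f"c{i}" for i in range(19)), 128.0, label=1)
        es = epoch(rec, window=1, step=1)
        assert es.n_instances == 50_000
        assert np.all(es.labels == 1)

    @given(n=st.integers(10, 500), window=st.integers(1, 10), step=st.integers(1, 10))
    def test_count_formula(self, n, window, step):
        if window > n:
            return
        rec = Recording(np.zeros((2, n)), ("a", "b"), 128.0, label=0)
        es = epoch(rec, window, step)
        assert es.n_instances == (n - window) // step + 1

    def test_ten_second_windows(self):
        rec = Recording(np.zeros((2, 1280)), ("a", "b"), 128.0, label=0)
        assert epoch(rec, 128, 128).n_instances == 10

    def test_window_validation(self):
        rec = Recording(np.zeros((2, 100)), ("a", "b"), 128.0)
        with pytest.raises(ValueError):
            epoch(rec, 0, 1)
        with pytest.raises(ValueError):
            epoch(rec, 200, 1)

    def test_epoch_values_match_slices(self):
        rng = np.random.default_rng(1)
        rec = Recording(rng.standard_normal((3, 50)), ("a", "b", "c"), 128.0, label=0)
        es = epoch(rec, window=10, step=7)
        for i in range(es.n_instances):
            np.testing.assert_array_equal(es.epochs[i], rec.data[:, i * 7:i * 7 + 10])


class TestTimeDomainFeatures:
    def test_constant_epoch(self):
        es = make_epochset(np.full((2, 3, 16), 4.2))
        fm = time_domain_features(es)
        vals = dict(zip(fm.feature_names, fm.values[0]))
        assert vals["mean_c0"] == pytest.approx(4.2)
        assert vals["variance_c1"] == 0.0
        assert vals["skewness_c2"] == 0.0

    def test_moment_formulas_match_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5, 2, 31))
        fm = time_domain_features(make_epochset(x))
        for i in range(5):
            for c in range(2):
                sig = x[i, c]
                row = dict(zip(fm.feature_names, fm.values[i]))
                assert row[f"mean_c{c}"] == pytest.approx(sig.mean())
                assert row[f"variance_c{c}"] == pytest.approx(sig.var())
                assert row[f"skewness_c{c}"] == pytest.approx(sps.skew(sig))

    def test_12345_epoch(self):
        es = make_epochset(np.tile(np.arange(1.0, 6.0), (1, 2, 1)))
        fm = time_domain_features(es)
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["mean_c0"] == 3.0
        assert row["variance_c0"] == pytest.approx(2.0)
        assert row["skewness_c0"] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 2, 21))
        a = time_domain_features(make_epochset(x)).values
        b = time_domain_features(make_epochset(-x)).values
        n_ch = 2
        np.testing.assert_allclose(b[:, :n_ch], -a[:, :n_ch])                  # means
        np.testing.assert_allclose(b[:, n_ch:2 * n_ch], a[:, n_ch:2 * n_ch])  # variances
        np.testing.assert_allclose(b[:, 2 * n_ch:], -a[:, 2 * n_ch:], atol=1e-12)  # skews


class TestFrequencyDomainFeatures:
    def test_single_bin_spectrum_zero_entropy(self):
        t = np.arange(128) / 128.0
        sig = np.sin(2 * np.pi * 16 * t)          # exactly bin 16 of the rfft grid
        es = make_epochset(sig[None, None, :])
        fm = frequency_domain_features(es)
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["spectral_entropy_c0"] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_spectrum_entropy_log2k(self):
        # craft a signal whose in-band periodogram is exactly uniform:
        # equal-amplitude sinusoids on every in-band bin
        n, fs = 128, 128.0
        freqs = np.fft.rfftfreq(n, 1 / fs)
        in_band = (freqs >= 4) & (freqs <= 40)
        t = np.arange(n) / fs
        sig = sum(np.cos(2 * np.pi * f * t) for f in freqs[in_band])
        es = make_epochset(sig[None, None, :])
        fm = frequency_domain_features(es)
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["spectral_entropy_c0"] == pytest.approx(np.log2(in_band.sum()), rel=1e-6)

    def test_alpha_sine_band_powers_match_periodogram(self):
        from scipy import signal as ss
        t = np.arange(256) / 128.0
        sig = np.sin(2 * np.pi * 10 * t)
        es = make_epochset(sig[None, None, :])
        fm = frequency_domain_features(es)
        row = dict(zip(fm.feature_names, fm.values[0]))
        bands = {k: row[f"bp_{k}_c0"] for k in ("theta", "alpha", "beta", "gamma")}
        assert max(bands, key=bands.get) == "alpha"
        freqs, pxx = ss.periodogram(sig, fs=128.0, detrend=False)
        expected = pxx[(freqs >= 8) & (freqs < 13)].sum()
        assert bands["alpha"] == pytest.approx(expected)

    def test_zero_power_epoch_entropy_sentinel(self):
        es = make_epochset(np.zeros((1, 2, 64)))
        fm = frequency_domain_features(es)
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["spectral_entropy_c0"] == 0.0

    def test_small_window_returns_none(self):
        es = make_epochset(np.zeros((2, 2, 4)))
        assert frequency_domain_features(es) is None


class TestConcatAndStandardize:
    def _blocks(self, n=20, n_ch=19, window=64, seed=0):
        rng = np.random.default_rng(seed)
        es = make_epochset(rng.standard_normal((n, n_ch, window)))
        t = time_domain_features(es)
        f = frequency_domain_features(es)
        spec = AutoencoderSpec(epochs=2, seed=0)
        ae = train_autoencoder(es.flattened(), spec)
        l = encode(ae, es.flattened(), es.labels)
        return l, t, f

    def test_full_width_184(self):
        l, t, f = self._blocks()
        fm = concat_features(l, t, f)
        assert fm.n_features == 32 + 57 + 95 == 184
        assert fm.tags[:32] == ["latent"] * 32
        assert set(fm.tags) == {"latent", "time", "freq"}

    def test_row_mode_width_89(self):
        l, t, _ = self._blocks()
        fm = concat_features(l, t, None)
        assert fm.n_features == 89
        assert fm.tags[-1] == "time"

    def test_label_mismatch_rejected(self):
        l, t, _ = self._blocks()
        t.labels = t.labels + 1
        with pytest.raises(ValueError):
            concat_features(l, t)

    def test_standardizer_train_stats(self):
        l, t, f = self._blocks(n=50)
        fm = concat_features(l, t, f)
        scaler = Standardizer.fit(fm)
        out = scaler.transform(fm)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-8)
        varying = fm.values.std(axis=0) > 0
        np.testing.assert_allclose(out.values.var(axis=0)[varying], 1.0, atol=1e-6)


class TestAutoencoder:
    def test_low_rank_reconstruction_beats_10pct(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((600, 5))
        x = z @ rng.standard_normal((5, 19)) + 0.01 * rng.standard_normal((600, 19))
        ae = train_autoencoder(x, AutoencoderSpec(epochs=50, seed=3))
        # truncated-SVD oracle: rank-32 linear floor is ~the noise level
        u, s, vt = np.linalg.svd(x - x.mean(0), full_matrices=False)
        svd_floor = (s[32:] ** 2).sum() / x.size
        assert ae.reconstruction_mse(x) <= 0.1 * x.var()
        assert ae.reconstruction_mse(x) >= svd_floor - 1e-12

    def test_zero_epochs_equals_initialization(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 10))
        ae = train_autoencoder(x, AutoencoderSpec(epochs=0, seed=5))
        fresh = type(ae)(10, AutoencoderSpec(epochs=0, seed=5))
        assert ae.reconstruction_mse(x) == fresh.reconstruction_mse(x)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((80, 12))
        spec = AutoencoderSpec(epochs=5, seed=9)
        a = train_autoencoder(x, spec)
        b = train_autoencoder(x, spec)
        assert a.history == b.history

    def test_nonfinite_input_rejected(self):
        x = np.ones((10, 4))
        x[3, 2] = np.nan
        with pytest.raises(ValueError):
            train_autoencoder(x, AutoencoderSpec(epochs=1))

    def test_loss_decreases(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((200, 8))
        ae = train_autoencoder(x, AutoencoderSpec(epochs=10, seed=0))
        assert ae.history[-1] < ae.history[0]


class TestEncode:
    def test_width_32_and_tags(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 10))
        ae = train_autoencoder(x, AutoencoderSpec(epochs=2, seed=0))
        fm = encode(ae, x, np.zeros(40, int))
        assert fm.n_features == 32
        assert all(t == "latent" for t in fm.tags)

    def test_duplicate_rows_identical_latents(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 10))
        x[5] = x[3]
        ae = train_autoencoder(x, AutoencoderSpec(epochs=2, seed=0))
        z = ae.encode(x)
        np.testing.assert_array_equal(z[5], z[3])

    def test_width_mismatch(self):
        rng = np.random.default_rng(2)
        ae = train_autoencoder(rng.standard_normal((30, 10)), AutoencoderSpec(epochs=1, seed=0))
        with pytest.raises(ValueError):
            encode(ae, rng.standard_normal((5, 12)), np.zeros(5, int))

    def test_linear_probe_on_separated_classes(self):
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 150)
        x = rng.standard_normal((300, 19))
        x[y == 1] += 1.5
        ae = train_autoencoder(x, AutoencoderSpec(epochs=20, seed=0))
        z = ae.encode(x)
        probe = LogisticRegression(max_iter=500).fit(z, y)
        assert probe.score(z, y) > 0.8
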