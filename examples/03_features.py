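"""Build the unified feature vector: autoencoder latents + moments + spectra.

Each 1-second epoch becomes 184 features: 32 latent codes from the
128-64-32 bottleneck autoencoder, 3 moments per channel (57), and 4 band
powers + spectral entropy per channel (95).
"""

from eegadhd import (
    AutoencoderSpec,
    Standardizer,
    SynthConfig,
    concat_epoch_sets,
    concat_features,
    encode,
    epoch,
    frequency_domain_features,
    generate_recording,
    time_domain_features,
    train_autoencoder,
)

cfg = SynthConfig(n_samples_per_class=128 * 120, seed=3)   # 120 s per class
es = concat_epoch_sets([epoch(generate_recording(cfg, c), 128, 128) for c in (0, 1)])
print(f"{es.n_instances} one-second epochs of {es.n_channels} channels")

ae = train_autoencoder(es.flattened(), AutoencoderSpec(epochs=15, seed=0))
print(f"autoencoder reconstruction loss {ae.history[0]:.2f} -> {ae.history[-1]:.2f}")

latent = encode(ae, es.flattened(), es.labels)
fm = concat_features(latent, time_domain_features(es), frequency_domain_features(es))
fm = Standardizer.fit(fm).transform(fm)
counts = {t: fm.tags.count(t) for t in ("latent", "time", "freq")}
print(f"unified feature matrix: {fm.n_instances} x {fm.n_features} ({counts})")

theta_cols = [i for i, n in enumerate(fm.feature_names) if n.startswith("bp_theta")]
gap = fm.values[fm.labels == 1][:, theta_cols].mean() - \
    fm.values[fm.labels == 0][:, theta_cols].mean()
print(f"mean standardized theta band power, ADHD minus control: {gap:+.2f} SD — "
      "the class contrast the classifier will exploit")
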