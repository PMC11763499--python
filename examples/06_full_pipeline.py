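"""Run the whole pipeline end to end at a small scale and print the report.

simulate -> bandpass + ICA -> epochs -> autoencoder + moments + spectra ->
RSA selection -> attention ResNet -> metrics vs ensemble baselines.
At this miniature scale (400 one-second epochs) the run takes well under a
minute; use `eegadhd.pipeline.demo_config()` for the 5,000-instance version.
"""

from eegadhd import AutoencoderSpec, ModelConfig, PipelineConfig, RSAConfig, SynthConfig
from eegadhd.pipeline import make_report, run_pipeline

cfg = PipelineConfig(
    seed=5,
    synth=SynthConfig(n_samples_per_class=128 * 200, seed=0),   # 200 epochs/class
    autoencoder=AutoencoderSpec(epochs=5),
    rsa=RSAConfig(n_pop=10, n_iter=15, alpha_fitness=0.99),
    model=ModelConfig(blocks_per_stage=(2, 2), stage_kernels=(7, 5),
                      stage_channels=(16, 32), epochs=25, batch_size=32,
                      learning_rate=3e-3),
    baseline_n_estimators=50,
    out_dir="scratch/example_runs",
    save_feature_csv=False,
)
result = run_pipeline(cfg)
print(make_report(result.run_dir))
print("\nall artifacts (config echo, selection, checkpoint, ROC, log) are in",
      result.run_dir)
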