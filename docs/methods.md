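# Methods

## Signal model of the synthetic generator

Each class is synthesized as a sum over the canonical EEG bands —
delta (1–4 Hz), theta (4–8), alpha (8–13), beta (13–30), gamma (30–45) — of
independently drawn Gaussian noise band-limited by a zero-phase 4th-order
Butterworth, scaled so each band's variance share matches the configured
class profile, then scaled to `amplitude_uv` (default 10 µV RMS) with white
sensor noise (`noise_sd`, default 1 µV) added. Default class profiles:
control `{delta 1, theta 1, alpha 1.2, beta 1, gamma 0.4}`, ADHD
`{delta 1, theta 3, alpha 1.2, beta 0.5, gamma 0.4}` — the direction (not the
magnitude) of the classical theta/beta-ratio finding. The contrast is a dial:
the test suite verifies the between-class theta effect size grows
monotonically with the configured ratio.

Artifacts are injected by a separate pure function so artifact-free ground
truth survives: blinks are 300 ms squared-cosine bumps (default 120 µV,
5/min) projected through a decaying scalp topography (Fp1/Fp2 1.0, other
frontal 0.4, central 0.15, posterior 0.05 — blinks volume-conduct, and a
strictly two-channel artifact would leave the median-channel SNR insensitive
to cleaning); line noise is a fixed-frequency sinusoid (default 50 Hz, 4 µV)
with per-channel random phase.

**What this emulates and what it does not.** The generator reproduces the
*statistical* structure the pipeline assumes — class-dependent band power,
frontal transients, mains contamination, the 19-channel/128 Hz tabular
layout — not physiological EEG: no forward-modelled sources, no non-
stationarity, no subject-level structure (recordings are single continuous
draws; how the original 50,000 rows related to its 121 participants is not
derivable, so no per-subject blocking is attempted), no task timing.
Consequently, passing end-to-end tests shows the pipeline is *correct and
able to learn a planted band-power contrast*; it says nothing about clinical
accuracy on real recordings, and the published 99.42% on the original
dataset is reproduced only at the metric-formula level, not re-derived from
data.

## Preprocessing

* Bandpass: zero-phase forward–backward Butterworth order 4 (effective 8),
  4–40 Hz, as second-order sections. Zero phase preserves waveform timing;
  linearity is asserted as a property test.
* ICA: FastICA (fixed-point, deflation), seeded; `k` defaults to the channel
  count so the reconstruction is exact when nothing is rejected.
* Component rejection replaces expert review with two automatic criteria,
  both configurable: |correlation| ≥ 0.6 between a component time-course and
  a blink surrogate (mean of Fp1/Fp2 low-passed at 4 Hz), or excess kurtosis
  > 10 (blinks are sparse and spiky; ongoing EEG is near-Gaussian; a
  sinusoid's kurtosis is negative, so line noise is deliberately left to the
  bandpass). Flagging every component is refused rather than returning an
  empty signal.
* The pipeline filters before ICA (the reverse order is a config switch; the
  source description is ambiguous on this point). Note the 4 Hz high-pass
  already removes most blink energy, which is why ICA validation tests run
  on unfiltered artifacted recordings.
* SNR is `10·log10(P_signal / P_residual)` per channel against a reference;
  a zero residual returns `+inf` as the documented sentinel.

## Features

Instances are epochs: `window=128, step=128` (1 s, non-overlapping) is the
scientific default; `window=1, step=1` reproduces the source's row-per-sample
layout, in which variance/skewness are defined as 0 and the spectral block is
absent (windows < 8 samples cannot resolve the bands). Moments are population
moments; spectral entropy is Shannon entropy (bits) of the periodogram
normalized over 4–40 Hz, 0 for a zero-power window. The autoencoder consumes
the flattened epoch (`channels × window`), so at window 1 it sees exactly the
19-value row. Standardization (z-score) and autoencoder fitting use the
training split only — asserted by construction in the pipeline, which splits
at the epoch level before any fitting.

Autoencoder: dense 128–64–32 encoder, mirrored decoder, ReLU, linear output,
MSE loss (MAE and Huber are config options), Adam at 1e-3, batch 256, 50
epochs, seeded. Training asserts the final loss improves on initialization.

## Reptile Search Algorithm

Implemented as printed where the source is unambiguous, and from the cited
origin algorithm where typography lost information:

* Initialization is `rand·(UB−LB)+LB` (the printed form collapses to
  `rand·UB` if read literally, contradicting its own description of bounds).
* `ES(τ) = 2·r3·(1−τ/T)` with `r3 ~ U(−1,1)` — the printed version omits τ,
  which would make the belly-walking phase schedule-free.
* The two exploitation rules (hunting coordination/cooperation) and the `P`,
  `R`, `μ` auxiliaries follow the origin algorithm; `α = β = 0.1`,
  `ϵ = 1e-10`, all in config.
* Greedy acceptance is strict (`<`), so ties keep the incumbent and the
  best-so-far trace is non-increasing by construction; candidates are clipped
  to bounds every iteration; non-finite objective values reject the candidate
  and are counted.

Feature selection binarizes positions with `sigmoid > 0.5` on recommended
bounds [−4, 4]; an empty mask is repaired to the single largest-sigmoid
coordinate. The wrapper fitness is
`alpha_fitness · cv_error + (1 − alpha_fitness) · |selected|/D` with
`alpha_fitness = 0.99` and a stratified 3-fold 5-nearest-neighbour surrogate.
The CV split uses its own fixed seed (`cv_seed`), not the optimizer seed:
the fitness landscape must be one fixed function of the data, or runs with
different seeds are optimizing different objectives and cannot be compared
to the enumeration oracle. Fitness values are cached per mask, and on large
inputs an optional seeded class-balanced subsample (`fitness_subsample`,
pipeline default 2000) bounds the wrapper cost.

Pilot behaviour (recomputed by the test suite): 5-D sphere median best 0 at
N=30/T=200; 1-D shifted quadratic within 0.005; D=8 wrapper problems match
the 255-mask enumeration optimum in ≥ 9/10 seeds.

## Attention ResNet

"Eighteen residual layers" is read as 18 convolutional layers on residual
main paths: 9 basic blocks (2 convolutions each) in 4 stages of 2/2/3/2
blocks, channels 16/32/64/128. Kernel sizes {3,5,7} are assigned per stage
(7, 5, 3, 3) — wide early, narrow late — rather than as parallel branches;
stride 2 at each stage transition with same padding; batch norm + ReLU;
1×1 strided projection shortcuts where shapes change (not counted in the
audit); global-average-pool head to 2 classes.

Attention: after every stage, a spatial gate (squeeze → bottleneck MLP →
softmax over channels) and a temporal gate (position-wise linear score →
softmax over positions), multiplied elementwise into the feature map.
Both scoring layers are zero-initialized, so an untrained gate is exactly
uniform ("do no harm" start) and at sequence length 1 the temporal gate is
the bit-exact identity. Weights are simplex-valued per instance by
construction. In feature mode the selected D-vector is presented as a 1×D
sequence (spatial attention then weights learned filter channels); in
raw-epoch mode an optional input-level spatial gate weights the EEG channels
directly, and tests verify trained gates concentrate on planted signal
channels/intervals.

Training: softmax cross-entropy, Adam 1e-3, batch 256, 30 epochs default,
seeded shuffling; divergence aborts. Prediction: softmax probabilities;
label 1 only if P(1) > 0.5, so an exact tie yields class 0. Note the
sum-to-one gates attenuate activations by ~1/C and ~1/L; interior batch
norms re-normalize this, but optimization is slower than for the plain
ResNet ablation — small-sample experiments in the tests use smaller batches
(64) or a 3e-3 rate to compensate, as noted per test.

## Evaluation

Positive class = ADHD = 1. All rates derive from integer counts; zero-
denominator rates return a NaN `UNDEFINED` sentinel, never silent 0. The
misclassification rate is computed as `1 − accuracy`, which equals the
(FP+FN)/S definition exactly in real arithmetic and makes the complement
invariant hold exactly in floating point. `balanced_auc = (TPR+TNR)/2`
(balanced accuracy, also reported ×100) is kept separate from the
trapezoidal ROC AUC computed by threshold sweep — the two are different
statistics and reports carry both, labeled. The split is stratified (the
published test matrices are near-balanced at 5010/4990). Repeated-run
summaries use the t-interval `mean ± t₀.₉₇₅,ₙ₋₁·SD/√n`, exact degenerate
intervals for constant runs; model comparison is a Welch two-sample t-test
(the source reports p-values without naming a procedure), with p = 1 by
convention for identical zero-variance samples.

## Problem sizes and determinism

The shipped demo scale (`pipeline.demo_config`) is 5,000 one-second
instances (2,500 per class), a 4-block/8-convolution network trained 20
epochs, RSA at N=15/T=40 with a 2,000-instance fitness subsample — chosen as
the smallest scale at which every stage operates in its intended regime while
a full run stays in the minutes range on a single CPU. One global seed
derives per-stage seeds as `SHA-256("{seed}:{stage}") mod 2^31`, decoupling
the random streams; a re-run with the same config produces a byte-identical
report. The examples use even smaller sizes (hundreds of epochs) purely for
illustration.

## Known limitations

* Synthetic-only validation: no claim transfers to clinical EEG (see above).
* The autoencoder and classifier are NumPy implementations tuned for
  correctness and small problems, not GPU-scale throughput.
* Automatic ICA criteria are a reproducible stand-in for expert judgment and
  will mis-flag atypical components outside the blink/kurtosis pattern.
* The row-per-sample layout (window=1) supports no spectral features; its
  instances are single voltage samples, and classification in that mode
  leans entirely on amplitude statistics learned by the autoencoder.
* Whether the original study trained its classifier on selected features or
  raw windows is not determinable from its description; feature mode is the
  default here and raw-epoch mode is provided.
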