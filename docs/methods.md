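# Methods

`mdefusion` implements a multi-domain EEG classification method for
schizophrenia recognition: time-frequency and spatial features extracted
per 2-s analysis window are fused by a half-split crossover sparse
autoencoder (HCSAE) and classified by a bidirectional attention LSTM
(BALSTM), with strictly subject-independent evaluation. This note records
the model, the choices made where the design was genuinely open, and what
the synthetic cohorts do and do not establish.

## Signal model and preprocessing

Input recordings are multichannel scalp EEG on the 10–20 system, either
19 channels (Fp1…P8 plus FCz, CPz, Oz) or the 16-channel subset. The
preprocessing chain is:

1. **Band-limiting** to (0, 100) Hz with a zero-phase Butterworth filter
   (`sosfiltfilt`, default order 8). A 0-Hz high-pass edge is vacuous, so
   the band-pass degenerates to a low-pass; at sampling rates where 100 Hz
   is not representable the edge is clamped to 0.45 fs.
2. **Normalization**: per-channel z-score over the recording. Constant
   channels are a hard error naming the channel.
3. **Montage harmonization**: 16-channel recordings get FCz, CPz and Oz
   estimated by spherical spline interpolation (Perrin-style, order m=4,
   Legendre series truncated at 20 terms, ridge 1e-5 on the spline
   system), then all recordings are put in the canonical 19-channel order.
   Electrode coordinates come from a packaged unit-sphere table derived
   from 10–20 placement geometry (36° arc steps; intermediate sites as
   spherical midpoints). The implementation agrees with an independent
   Perrin implementation to ~1e-5 relative on random spatial patterns.
4. **Windowing**: 2-s windows with 1-s stride, so a recording of T seconds
   yields floor((T−2)/1)+1 windows (899 per 15-min recording, 59 per
   1-min recording).
5. **Subject-independent split**: per class, floor(0.8·n) subjects train;
   the remainder divides equally between validation and test, an odd
   leftover alternating val-first across classes. This rounding rule is
   fixed by the canonical cohort arithmetic (14+14 → 22/3/3 subjects,
   39+39 → 62/8/8; segment totals 19,778/2,697/2,697 and 3,658/472/472).
   Class imbalance is handled by random *subject-level* under-sampling,
   which preserves subject independence. Segments are shuffled within
   partitions under the plan seed.

## Features

**F1 (time-frequency)** — per channel, a full wavelet-packet decomposition
(default db4, depth 3, periodization mode). The terminal-node coefficient
sequences are frequency-ordered; with an orthogonal wavelet the transform
is orthonormal, so coefficient energy equals signal energy (Parseval) and
the decomposition is exactly invertible — both are tested invariants. A
`cwt` mode implements the continuous transform directly: for scale β and
shift χ, (1/√β)·Σₜ x(t)·ψ((t−χ)/β) with a real Morlet mother wavelet
ψ(u) = exp(−u²/2)cos(5u) and unit sample spacing. The wavelet family and
depth are not externally constrained; db4/depth-3 was chosen as a common
EEG default giving eight subbands that straddle the canonical rhythm
bands at 128–250 Hz sampling.

**F2 (spatial)** — activations of a single unmixing matrix J estimated by
fixed-point ICA (log-cosh/tanh contrast, deflation; backed by
scikit-learn's FastICA) on the *training partition only*, then applied
unchanged everywhere: F2 = J(X − mean). Components default to the rank of
the pooled training covariance — after interpolation the harmonized
montage is rank-deficient (interpolated channels are linear combinations
of measured ones), so whitening stops at the achievable rank. Fitting
pools training windows along time and subsamples to 50k time points.

F1 and F2 are bundled per segment with time axes aligned (nearest-index
upsampling of the subband sequences to the sample grid). Model inputs are
z-scored per feature channel with training-partition statistics.

## Network

**Temporal condensation.** Before the network, feature time axes are
pooled into a fixed number of bins (`seq_len`, default 32) by averaging
*magnitude* envelopes. Wavelet subband coefficients and unmixed source
activations are band-pass waveforms; a signed mean cancels toward zero
and erases exactly the amplitude structure that separates the classes, so
the envelope is what enters the network. How the fused features are
presented to the recurrent stage is not externally constrained; a fixed
short sequence makes CPU training tractable without touching the
architecture itself.

**HCSAE.** Each stream passes a 1×1 convolution (channel transformation to
`abstract_channels`, default 32) and then `n_1x3_layers` (default 2)
same-padded 1×3 convolutions learning temporal structure, tanh after
every layer — tanh, not sigmoid, for its symmetric (−1,1) range matching
the signed fluctuations of EEG-derived features. The two abstracted maps
A and B are bisected along channels and cross-combined: P = [A₁, B₂],
Q = [B₁, A₂]. The crossover only regroups values (an exact multiset
invariant in the tests). Sparsification is inverted dropout
(Bernoulli keep-probability 1−q, scaling 1/(1−q), default q = 0.3):
expectations are preserved at training time and inference is the
identity. No KL activation penalty is used — continuous-valued feature
maps do not match a near-0/1 mean-activation prior. P and Q then fuse in
a small tree: a 1×1 convolution + tanh on each, concatenation, and a
final 1×1 convolution + tanh producing the latent code
(`latent_channels`, default 64). The decoder restores the concatenated
abstracted width with a 1×1 convolution and max-pools time by 2; the
reconstruction target is the same-pooled concatenated abstracted input
(treated as constant in the loss), and the reconstruction error is mean
squared. The exact tree depth and widths are free parameters; the
defaults were chosen for plausibility, and matching any particular
global parameter count is explicitly not attempted.

**BALSTM.** Three stacked bidirectional LSTM layers, 64 hidden units per
direction. Cells use the standard update — gates p, f, o = σ(...),
candidate tanh(...), c_t = f⊙c_{t−1} + p⊙tanh(g), h_t = o⊙tanh(c_t) —
with recurrent weights included: a gate without recurrence would be
inconsistent with a memory update that propagates hidden state. The first
two layers in each direction are internal hidden layers whose outputs are
enhanced by input-guided attention: the layer's own input is linearly
projected to the hidden width (the projection resolves the dimension
mismatch between input and hidden spaces), softmaxed across the feature
dimension per time step, and multiplied elementwise into the hidden
state. Attention is separate per direction and per layer. The final
layer's forward and backward sequences are concatenated (width 128).
Initialization: orthogonal recurrent blocks, scaled-uniform input
weights, forget-gate bias 1, all seeded.

**Head and loss.** Per-step outputs are mean-pooled over time and a single
fully connected layer produces two-class logits. The training loss is
cross-entropy + λ·reconstruction-MSE with λ = 0.1 (the combination weight
is a free parameter; 0.1 keeps the auxiliary term an order below the
classification term at initialization). Optimization is Adam at learning
rate 1e-3, batch 64, 200 epochs, with the learning rate decayed ×0.9
every 20 epochs ("decay 0.9" read as an exponential learning-rate
schedule; it is exposed in config in case a different reading is wanted).
No early stopping; the best-validation checkpoint is retained.

The networks run on a compact in-package reverse-mode autodiff core over
numpy (float32). Every primitive's gradient is validated against central
finite differences, and the composed network against a float64
finite-difference probe at 1e-4 relative.

**Complexity accounting.** `count_params_flops` reports the exact
trainable-scalar count and a per-forward FLOP tally (2 FLOPs per
multiply-add, plus bias adds and a nominal constant for nonlinearities),
validated against hand audits on single layers. Matching any particular
global Params/FLOPs figure depends on layer widths this package chooses
freely, and is a non-goal.

## Evaluation

Segment-level metrics are the five standard ratios from the 2×2 confusion
table with the patient class positive: accuracy, precision, recall,
specificity, F1 (harmonic mean of precision and recall). Undefined ratios
are reported as NaN with a warning, never silently as 0. Percentages are
rounded half-up to one decimal (two for subject-level accuracies).

Subject-level scoring uses the rare-event rule: a subject is recognized
correctly iff *strictly more than* 95% of their segments are classified
correctly (a fraction of exactly 0.95 fails). Incorrect subjects enter
the subject-level confusion matrix under the flipped label — a convention
that turns the correctness rule into a full 2×2 table. Worked examples:
14/14 patients + 12/14 controls → 26/28 = 92.86%; 35/39 + 37/39 → 72/78
= 92.31%.

## Synthetic cohorts

The generator emulates two-class resting-state cohorts: per channel, one
random-phase sinusoid per canonical band (delta 1–4, theta 4–8, alpha
8–13, beta 13–30, gamma 30–45 Hz) with amplitude ∝ 1/f at the band
centre (amplitude scale 10 µV·Hz, so ~1 µV in alpha), plus white Gaussian
noise (sd 1 µV). The patient group scales one band's amplitude by
√power_ratio (band power by power_ratio) and receives a shared latent
oscillation mixed into all channels with weight corr_shift, giving ICA a
recoverable spatial structure. Presets mirror the two public-cohort
geometries: 14/group × 900 s × 19 channels (250 Hz default) and 39/group
× 60 s × 16 channels (128 Hz default); the sources do not state sampling
rates, so both are configurable. Default class effect: alpha,
power_ratio 3, corr_shift 0.2.

What passing tests show: the pipeline recovers a *known, injected,
band-power class difference* across held-out subjects essentially
perfectly. What they do not show: performance on real patient EEG, whose
class differences are weaker, non-stationary, multi-band and confounded
by artifacts (no blink/EMG simulation, no biophysical forward model).
The generator is a correctness and plumbing instrument, not a claim
about clinical difficulty.

## Problem sizes used in checks

The end-to-end recovery experiments use the cohort the package defines
for that purpose — 20 subjects/group, 60 s at 128 Hz, alpha power ×3 —
with a reduced network profile (abstract 16, one 1×3 layer, latent 32,
hidden 32, seq_len 8, batch 128, 50 epochs) chosen once so a full run
trains in CPU minutes; the success criterion is held-out subject accuracy
≥ 0.9 in at least 2 of 3 seeds. Training histories, determinism, and
checkpoint round-trips are tested on miniature configurations of the same
architecture.

## Numerical notes and edge cases

- WPT uses periodization mode; other padding modes break exact Parseval.
- Dropout masks draw from a dedicated seeded generator; inference never
  consumes randomness, so eval-mode forwards are bitwise reproducible.
- The spline system carries a ridge term (1e-5); interpolation at a
  position coincident with a measured electrode therefore smooths
  slightly and exact recovery is only guaranteed for constants.
- Max-pooling truncates an odd trailing time step.
- `split_subjects` requires ≥3 subjects per class; a remainder of 1
  places that class's held-out subject in val or test alternately.
- EDF fixtures store 16-bit samples against a per-channel symmetric
  physical range written into the 8-character header fields; round-trip
  error is bounded by the quantization step of that stored range.

## Known limitations

- The CWT scale grid, wavelet family and WPT depth are module defaults,
  not externally fixed values.
- Whether the spatial features should be the unmixing matrix itself or
  the unmixed activations is ambiguous in the source description;
  activations are used (they carry per-segment temporal information).
- The subject-level confusion convention for incorrect subjects (flipped
  label) is one of several defensible choices.
- Training determinism is guaranteed within a fixed BLAS/thread
  configuration; cross-machine bitwise identity is not promised.
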