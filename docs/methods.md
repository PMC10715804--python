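# Methods

This note documents the model, the numerical choices, and the synthetic
study conditions the package is validated on.  It is the maintainers'
account of *why* the code is the way it is; the README covers *how to use*
it.

## Problem setting

The unit of data is a signal **epoch**: a fixed-length window `x ∈ R^{C×N}`
of a multichannel recording sampled at `fs` Hz (for sleep EEG, 30-second
windows; stages coded 0=W, 1=N1, 2=N2, 3=N3, 4=R in AASM order).  Subjects
contribute many epochs; all splits (pretrain / train / test) are made at
the subject level so that no individual leaks across sets, and the pretrain
split is always stripped of labels before it reaches the optimizer.

## Self-supervised objective

Two independently augmented views of the same epoch form a positive pair.
The online networks `f_θ` (encoder) and `g_θ` (projector) produce the
anchor `z′`; the target networks `f_φ, g_φ` — structurally identical,
updated only by the exponential moving average `φ ← λφ + (1−λ)θ` — produce
the positive `z″`.  Both are L2-normalized.  Similarity is the Gaussian
kernel `sim(a,b) = exp(−‖a−b‖²/(2σ²))`, a strictly increasing function of
cosine similarity on unit vectors, and the per-anchor loss is

    [ sim(z′, z_w) + δ − sim(z′, z″) ]₊

with the **world representation** `z_w` as the single negative reference.
Three variants are implemented:

* `contrawr` — uniform mean of the batch's target projections;
* `contrawr_plus` — per-anchor softmax-weighted mean, weights
  ∝ `exp(⟨z_k, z′⟩/T)`; the weights use the normalized projections, so the
  inner product is cosine similarity.  `T → ∞` recovers the uniform mean
  and `T → 0⁺` degenerates to the single nearest member (both asserted in
  tests);
* `avg_knn_topx` — mean of the X batch members nearest the anchor; the
  selected members are summed in ascending batch index so `X = M` is
  bitwise identical to `contrawr`, and ties break toward the smaller index
  for determinism.

`z″` and `z_w` are treated as constants under differentiation
(stop-gradient): only the anchor branch receives gradients, matching the
two-branch online/target pipeline.  The batch mean *includes* the anchor's
own positive by default — the average is an unbiased estimate of the data
mean and nothing in the objective requires exclusion — but
`exclude_self=True` is available.

At `σ = 2` the difference of two similarities sharing an anchor is bounded
by `1 − exp(−2²/(2σ²)) = 1 − e^{−1/2} ≈ 0.3935` (the diameter of the unit
sphere is 2), so margins `δ` below 0.1 leave the hinge nearly always
active; the configuration warns (not errors) in that regime.  Default
hyperparameters are `σ = 2`, `T = 2`, `δ = 0.2`, weight decay `1e−4`,
EMA `λ = 0.99` (a conventional value; the EMA rate is not otherwise
pinned down), with Adam as the optimizer — the objective only fixes the
learning rate `η` and weight decay, and Adam is the field's default for
this kind of encoder.

## Augmentations

Four label-preserving views, applied per view as a uniformly random
non-empty subset of the enabled operations in the fixed order
bandpass → noising → flipping → shifting (composition is beneficial, but no
particular per-view sampling law is canonical; the uniform-subset rule is
this package's choice).  Flipping is never applied alone: swapping
symmetric channels of an otherwise identical signal gives a view pair with
no usable contrast.

* **bandpass** — order-1 Butterworth, default 0.5–30 Hz (the standard
  sleep-EEG band), applied forward-backward (zero phase, so it commutes
  with shifting; the effective magnitude response is the squared order-1
  response).
* **noising** — white noise masked in the frequency domain to a randomly
  chosen low ([0, 2] Hz) or high ([fs/4, fs/2] Hz) band, scaled to a
  per-channel SNR drawn uniformly from 5–20 dB.  Mimics drift and
  high-frequency contamination.
* **flipping** — swaps homologous left/right channel pairs (default:
  adjacent pairs (0,1), (2,3), ...).
* **shifting** — circular shift by up to ±fs/2 samples.  Circular rather
  than zero-padded so per-channel energy and spectrum are preserved
  exactly and the operation is exactly invertible.

Every stochastic choice is a pure function of the supplied seed; the
training loop derives per-step seeds from the model's `random_state`, so a
whole pretraining run is bitwise reproducible.

## Encoder and projector

The encoder is a short-time Fourier transform front-end followed by a small
2-D convolutional network.  STFT defaults: Hann window of `2·fs` samples,
hop `fs/2`, magnitude with `log(1+·)` compression — standard sleep
spectrogram practice; frames start at sample 0 and only complete frames are
kept (`T = ⌊(N−window)/hop⌋ + 1`, `F = window/2 + 1`).  The network is one
stem convolution plus three (conv → ELU → 2×2 max-pool) blocks and a global
average pool; channel widths default to (4, 8, 16, 32) at desk scale
(full-scale profile: (8, 16, 32, 64)), 3×3 kernels, so the representation
dimension `d` equals the last width.  The projector is a two-layer
perceptron `d → 64 → 32` with ELU.  The configuration validates that the
spectrogram survives three pools (both axes ≥ 8 bins) and fails fast
otherwise.

The networks are implemented in a minimal numpy engine (`contrawr.nn`):
convolution as patch-gather + one GEMM (with numba-jitted gather/scatter
and a pure-numpy fallback), branch-free ELU, tie-stable max pooling, Adam
with coupled L2 weight decay, He-normal initialization keyed by a seed.
Backward passes are verified against central-difference numeric gradients
in `tests/test_nn.py`.  There is no dropout or batch normalization, so
training and inference forwards are identical and deterministic.

## Evaluation protocol

* **Linear probe** — encode the labeled splits with the frozen encoder,
  standardize, fit multinomial logistic regression.  The L2 strength is
  chosen over a small grid (C ∈ {0.01, 0.1, 1, 10}) on a 25 % stratified
  validation fold carved from the training features, then refit on the full
  training split; when the training split is too small to stratify, C = 1.
  Reported: overall accuracy, the K×K confusion matrix (rows = truth) and
  per-class recall for diagnostics.
* **Supervised reference** — the same encoder plus a 2-layer head
  (`d → 128 → K`, ELU) trained end-to-end with cross-entropy on the
  labeled training split only.
* **Untrained baseline** — the probe on a freshly initialized encoder.
  Random spectrogram convolutions are already informative features, so this
  baseline is far above chance; the value of pretraining is measured as the
  paired improvement over it.
* **Label-fraction sweep** — test subjects held fixed per seed; for each
  fraction `ceil(f · n)` of the remaining subjects are labeled training
  subjects (nested across fractions) and the rest pretrain without labels.
  Any `f > 0` therefore yields at least one training subject, and a
  fraction that exhausts the pretrain set is an error.

## Synthetic study conditions

The generator emulates the *spectral* structure of staged sleep EEG:
each class is a sum of band-limited oscillations (FFT-masked white noise
rescaled to an exact RMS amplitude) plus white noise.  Default stage
analogues: W → alpha 10 Hz; N1 → low-amplitude theta 6 Hz; N2 → sigma
13 Hz; N3 → high-amplitude delta 1.5 Hz; R → mixed 5 + 20 Hz.  Channels
come in mirror pairs sharing the oscillatory component (noise independent),
so channel flipping is label-preserving by construction.  Each subject
carries a log-normal gain (SD 0.2) and a per-class band-center jitter
(SD 0.3 Hz), which makes within-subject epochs measurably more alike than
between-subject ones and justifies subject-level splitting.

Default conditions: 5 classes, 40 subjects × 50 epochs, 4 channels,
N = 3000 samples at 100 Hz, noise SD 1.0.  With these settings a plain
bandpower + logistic classifier reaches ≥ 0.9 accuracy — the ceiling the
learned encoder is measured against — and classes are balanced exactly.

What the generator does **not** emulate: sleep-architecture stage
sequencing, artifacts (EMG/EOG, electrode pops), montage geometry, or
inter-recording hardware variation.  Passing tests therefore show the
pipeline learns spectral class structure from unlabeled data under
realistic augmentations — not that it reproduces clinical accuracies on
real polysomnography.

## Scale choices and determinism

Desk-scale defaults (batch 32, 30 pretraining passes, widths halved,
Adam lr 1e−3) keep the full pretrain → probe protocol at minutes on one
CPU; the full-scale profile (batch 256, 100 passes, lr 2e−4, full widths)
is available via `--profile paper` in the CLI.  The end-to-end trend test
uses a further scaled-down sweep (100 subjects × 10 epochs, N = 1000,
10 passes, 3 seeds, fractions 1–10 %).  All reported numbers are pure
functions of (data seed, split seed, model seed): dataset files are
byte-identical across reruns and loss histories are bitwise reproducible.

## Known limitations

* Only the world-representation family is implemented; memory-bank and
  predictor-head contrastive methods are deliberately out of scope.
* The numpy engine is single-threaded and desk-scale; it is not intended
  for full-night clinical corpora.
* EDF ingestion reads raw signals only (no annotation/hypnogram parsing);
  labels must arrive through the HDF5 container.
* `filtfilt` edge transients make the bandpass only approximately
  length-invariant near epoch boundaries; with 30-s epochs and an order-1
  filter the effect is negligible.
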