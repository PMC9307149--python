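# Methods

## The question

Conventional motor-imagery BCIs decode left- vs right-hand imagery from the
lateralization of sensorimotor-rhythm (SMR) power: imagining a hand movement
desynchronizes the mu (7–13 Hz) and beta (13–30 Hz) rhythm over the
contralateral motor cortex (ERD).  The standard decoder — Common Spatial
Patterns followed by linear discriminant analysis (CSP+LDA) — is a
*variance* reader: it can only use class differences in band-limited signal
power.  A substantial minority of users ("BCI-inefficient" users) never
produce a usable ERD contrast, yet may produce other class-dependent
activity, for example phase-locked potentials outside motor cortex, which a
variance reader is structurally blind to.  A convolutional network trained
on raw epochs has no such restriction.

This package implements the full comparison as a synthetic study: a
generator that produces both user archetypes with known ground truth, the
two decoding arms, and the cohort analysis that contrasts the per-subject
accuracy improvement ΔAccu = Accu_CNN − Accu_CSP+LDA between low and high
performers.

## Synthetic EEG generator (`mibci.simulate`)

One subject is 120 balanced left/right epochs over the 16-electrode
sensorimotor montage (F3, Fz, F4, FC1, FC5, FC2, FC6, C3, Cz, C4, CP1, CP5,
CP2, CP6, T7, T8), sampled at 250 S/s for 4 s per epoch at study scale, with
a 0.5–30 Hz acquisition band-pass (fifth-order Butterworth, applied
zero-phase).  Components:

* **Background**: per-channel pink (1/f-amplitude) noise, mixed across the
  montage by a smearing matrix `M_ij = exp(−d_ij / 0.35)` on a fixed 2-D
  layout (rows normalized to unit norm).  This gives the background a
  realistic spatial covariance, so CSP's whitening step has real work to do.
* **Sensorimotor rhythm**: an arciform mu oscillator — `sin φ(t) + 0.4
  sin(2φ(t) + 0.8)` with per-trial random phase and ±0.3 Hz frequency
  jitter around 10 Hz — whose beta-band content is the phase-locked first
  harmonic, as in real (non-sinusoidal) mu.  A shallow multiplicative
  envelope (5% pink-noise AM) models waxing/waning.  The oscillator enters
  the montage through the smearing column of C3 and (independently) C4 with
  amplitude `sqrt(snr) ×` background RMS.
* **ERD (efficient archetype)**: on trials of the contralateral hand the
  oscillator amplitude at that electrode is scaled by `sqrt(1 − erd_depth)`.
  `erd_depth` is the fractional band-variance reduction.
* **Inefficient archetype**: no ERD (`erd_depth = 0`).  Instead a
  subject-fixed, Hann-windowed low-frequency template (≈2–5.5 Hz, inside the
  acquisition band) is added at F3/F4/T7/T8 with **class-dependent
  polarity** (+ for left, − for right) and ~10% lognormal amplitude jitter,
  at `waveform_contrast ×` background RMS.  A sign flip leaves every
  second-moment statistic unchanged, so the two class covariances are
  *identical by construction*: CSP+LDA is blind to this signal in principle,
  not merely in practice, while any waveform-aware decoder can read the
  polarity.

### Default effect sizes, and what they are for

The cohort defaults are `erd_depth = 1.0`, `snr = 20` for efficient users
and `snr = 2`, `waveform_contrast = 0.6` for inefficient users (weak
resting SMR amplitude is the classic empirical correlate of BCI
inefficiency).  These are deliberately **idealized**: a complete
contralateral desynchronization of a strong rhythm makes the efficient
subjects essentially noise-free for both decoders, and the polarity
template makes inefficient subjects decodable only by the CNN.  The
generator is a mechanism demonstration with known ground truth, not a
calibrated model of real recordings: real EEG has far lower SNR,
non-stationarities, artifacts, and partial ERD.  Consequently, passing
tests show that the *pipelines* behave as the theory predicts on data with
the assumed structure (variance-based information vs variance-neutral
information); they do not predict absolute accuracies on real EEG.  The
spectral signature of real low performers is not characterized in the
literature this emulates; the polarity-template mechanism is one plausible
instantiation and is flagged as such.

## Preprocessing (`mibci.preprocess`)

Offline filters are fifth-order Butterworth applied forward–backward
(`sosfiltfilt`), which squares the magnitude response and cancels phase;
epoch-based offline analysis permits this and it avoids group-delay
distortion of the 4 s windows.  Edge transients are absorbed by the
filter's default odd-reflection padding.  The ML arm filters to 7–30 Hz
(the mu+beta range); a multi-band filter bank (FBCSP-style) is supported
and the single wide band is the default.  Epoch extraction uses half-open
sample intervals `[start·fs, end·fs)`.

## CSP+LDA arm (`mibci.cspline`)

Per-trial spatial covariances `E Eᵀ` are trace-normalized (removes
per-trial gain) and averaged by class.  CSP solves the generalized
eigenproblem `Σ₀ w = λ (Σ₀ + Σ₁) w`; the eigenvector rows of W, ordered by
descending λ, jointly diagonalize both class covariances, and the m first
plus m last filters (default m = 3) are retained.  Eigenvector signs are
fixed by making each filter's largest-magnitude coefficient positive; ties
in λ keep ascending index order.  Features are log-variances of the
projected components; LDA is the closed form `w = S⁻¹(μ₁ − μ₀)` with a
relative ridge (`1e-8 × trace(S)/d`) added only if S is ill-conditioned.
Both CSP and LDA are fitted strictly on the training fold of a stratified
80/20 split.

## CNN arm (`mibci.net`)

The network is conv(30 filters, 5×5, valid) → ReLU → maxpool(2×2, floor) →
flatten → dense(256) → ReLU → dense(128) → ReLU → dense(2) → softmax,
trained with Adam (lr 0.01, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on categorical
cross-entropy, batch size 264 — which exceeds the 96 training trials, so
each epoch is one full-batch step.  Each epoch enters as a
one-image-channel (electrodes × samples) array.  All layers are implemented
directly in numpy (im2col GEMM convolution; two-stage max pooling whose
backward pass routes gradients by equality masks), so every analytic
gradient is verifiable against central finite differences, which the test
suite does.

Numerical choices:

* **Initialization**: Glorot-uniform scaling for conv and hidden dense
  weights (the default of the frameworks this architecture is normally
  built in), zero biases, and a **zero-initialized output layer**.  At
  lr 0.01 the first full-batch Adam steps are large relative to the
  fan-in scale of the wide flatten→dense layer; starting the logits at zero
  removes a dead-network collapse mode (loss pinned at ln 2) that a
  randomly initialized output layer exhibits at this learning rate.
* **Input normalization**: per-channel z-scoring with training-fold
  statistics (flag `normalize`); at microvolt scale raw magnitudes stall
  ReLU training.  Statistics are never taken from the test fold.
* **No early stopping**; the per-epoch loss/accuracy history is recorded so
  overfitting is observable.  Training aborts with a divergence error
  (carrying the finite history) if the loss becomes non-finite.
* Cross-correlation semantics (no kernel flip); valid padding; floor
  semantics for pooling; probabilities clipped at 1e-12 inside the loss.

## Evaluation and cohort analysis (`mibci.evaluate`)

Accuracies and per-class F-scores (harmonic mean of precision and recall;
defined 0 when P + R = 0) are carried as percentages.  Both arms share the
identical stratified 80/20 partition per subject (same split seed).  The
subject's *online accuracy* — the ranking variable of the study — cannot be
re-derived offline, so its stand-in is the CSP+LDA test accuracy on a
separate calibration split (documented, configurable).  Subjects are
median-split on it: stable sort by (online accuracy, subject id), lower
half → "low"; with even n the groups are exactly equal regardless of ties.

Statistics: Shapiro–Wilk per group (scipy's implementation of the standard
normalizing approximation; verified against R's `shapiro.test` to 1e-4 in
the tests); a pooled-variance independent t-test (df = n₁ + n₂ − 2) on
ΔAccu between groups; a paired t-test (df = n − 1) of CNN vs CSP+LDA test
accuracy across the cohort; both with 95% CIs.  The improvement histogram
uses six 5-point bins from 1–5% to 26–30%, values rounded half-to-even to
the nearest integer percent; values outside land in an explicit overflow
bucket with a warning — at the synthetic effect sizes most inefficient
subjects' improvements (30–70 pp) do, by design.

## Problem sizes (desk scale)

The analysis drivers, the demonstration cohort and the heavy end-to-end
tests run at a reduced "desk scale": the full montage and 120-trial plan,
but 64 S/s and 1.5 s epochs (96 samples; the 0.5–30 Hz band sits under the
32 Hz Nyquist), with 60 training epochs for the CNN — on this synthetic
task full-batch Adam converges well before that.  A 20-subject cohort
(10 efficient, 10 inefficient) decodes in a few minutes on one CPU core.
Study-scale defaults (250 S/s, 4 s, 500 training epochs) remain the
configured defaults of `SimConfig` and `TrainConfig`.

## Known limitations

* No volume-conduction forward model, no EOG/EMG artifacts, no
  non-stationarity across trials, no trial scheduling or feedback loop —
  only the imagery epoch is generated.
* The effect-size regime is idealized (see above); cohort-level ΔAccu
  magnitudes (~0 vs ~30–70 pp) are much larger than anything real, so only
  signs and orderings, not magnitudes, are meaningful.
* The CNN endpoint after a fixed number of full-batch Adam epochs at
  lr 0.01 is chaotic in the weak-signal regime; per-subject accuracies for
  weak effects should be read as draws, and multi-seed medians are used
  wherever a scalar summary is needed.
* The independent t-test reports the standard pooled df; reported df in the
  emulated study's group comparison (t(26) for two groups of 27) is not
  reproducible under any standard convention.
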