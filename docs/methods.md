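# Methods

`ibistress` classifies short stretches of cardiac inter-beat intervals
(IBIs) as *stressed* or *non-stressed* by converting them into small images
and training a convolutional network.  This note records the model, the
parameter choices, the synthetic data it is validated on, and the numerical
decisions a maintainer would want to know about.

## From beats to images

**Input.** A subject's IBI sequence: beat timestamps (s) and beat durations
(s), in the two-column CSV dialect of the Empatica E4 wristband.  When a
"stressed" recording consists of several task segments (e.g. public
speaking followed by mental arithmetic), the segments are concatenated and
the join indices recorded; no analysis window ever spans a join.

**Range filter.** Durations outside a physiologic range are discarded
before encoding.  The default range is 0.6–1.2 s (100 down to 50 bpm);
both bounds are configurable.  Filtering is the only artifact handling —
no interpolation or resampling is performed, so windows are beat-indexed,
not time-indexed.

**Spatial images.** The filtered duration axis is discretised into 28
intervals.  Two schemes are available:

* `quantile` (default): edges at the 0/28 … 28/28 empirical quantiles of
  the filtered durations (equal-frequency bins).  Tied edges are
  deduplicated and the widest interval split until 28 intervals remain;
  with fewer than 28 distinct durations the scheme falls back to equal
  width and records a warning.
* `equal_width`: 28 even intervals over the configured range.

Each beat becomes a 28×1 one-hot column (1 in its interval, 0 elsewhere;
intervals are half-open, the top interval closed).  A 28-beat sliding
window (stride 1 by default, configurable) stacks 28 consecutive columns
into a 28×28 binary matrix — one image per window position, so an unbroken
segment of L beats yields ⌊(L−28)/stride⌋+1 images.  Row 0 is the
lowest-IBI interval; images are flipped vertically only at PNG export.
Internally pixels are {0,1}; grayscale export maps to {0,255}.  For any
experiment the binning scheme is fitted once on the pooled filtered
durations of all involved sequences (both conditions; all training
subjects in generic regimes) and applied unchanged to every sequence, so
train and test images always share bins.

**Frequency images.** Each spatial window f(x,y) is transformed by the
2-D discrete Fourier transform

F(u,v) = (1/MN) · Σₓ Σᵧ f(x,y) · exp(−j2π(ux/M + vy/N)),  M = N = 28,

computed with the FFT, shifted so the zero-frequency bin sits at the
matrix centre, reduced to log₁₀|F|, and min–max scaled to [0, 255] over
the finite entries.  Zero-magnitude bins (log → −∞) carry no energy and
map to 0.  The 1/MN factor cancels under the min–max scaling, so the
implementation applies the unnormalized FFT; a direct double-sum evaluator
(`dft2_reference`) serves as the test oracle for this equivalence.

Numerical decisions in the normalization:

* magnitudes below 10⁻¹² of the spectral peak are FFT round-off of exact
  zeros and are treated as zero energy (otherwise the log stretch would
  turn ~10⁻¹³ noise into full-contrast texture — e.g. a constant image
  must map to a single bright centre pixel);
* a finite log-range below 10⁻⁹ is degenerate: if zero-energy bins exist
  the finite bins map to 255 (they carry all the energy); an entirely
  constant finite spectrum maps to all zeros with a warning — never an
  exception;
* the classifier always receives the single-channel matrix (scaled to
  [0, 1]); colormapped PNG export is display-only.

## The classifier

A fixed small CNN for 28×28 single-channel images, implemented in NumPy
(im2col convolutions lowered to BLAS GEMMs, with numba-jitted gather/
scatter for the 3×3 taps and 2×2 pooling):

* 8 convolutions (3×3, size-preserving padding) with 32, 32, 64, 64, 128,
  128, 256, 256 feature maps; ReLU after each;
* a 2×2 max-pool (stride 2, floor) after every second convolution:
  spatial size 28 → 14 → 7 → 3 → 1;
* flatten (256 features), dense 256 + ReLU + dropout 0.5, dense 256 +
  ReLU + dropout 0.5, dense 1;
* the output unit is the logit of P(stressed); the hard label is
  stressed iff p ≥ 0.5 (ties resolve to stressed).

Training: mini-batch Adam (default lr 10⁻³, batch 32) on binary
cross-entropy with logits, fixed epoch count (default 150, no early
stopping), He initialisation.  The loss, optimiser and padding are this
package's choices — standard ones — as is inverted dropout.  A single
integer seed drives initialisation, shuffling and dropout, so a run is
exactly reproducible; probabilities for identical images within one batch
agree to float32 round-off (BLAS accumulation order depends on row
position), which is why prediction-equality tests use atol ≈ 10⁻⁶.

## Evaluation regimes

* **Person-specific**: one subject's images split 70/15/15
  (train/validation/test), stratified by class.  The default split samples
  images at random, which — with stride-1 windows — lets train and test
  windows share up to 27 of 28 source beats.  This mirrors the common
  construction of such experiments but inflates person-specific accuracy;
  a chronological split mode and an overlap-exclusion option are provided,
  and `leakage_report` quantifies the overlap of any split.
* **Generic**: three whole subjects held out for testing; the remaining
  subjects' pooled images are split 85/15 (stratified, seeded) into train
  and validation.  No test-subject image ever enters training — verified
  by the leakage report.
* **Calibrated-generic**: the generic split plus ⌊20%⌋ of each test
  subject's images per class moved into the training pool and removed from
  the test set.

All rounding is floor with the remainder to training.  Test performance is
reported as a confusion matrix (positive class = stressed) with accuracy
(TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP); a zero denominator yields NaN plus an `undefined` flag, never
a silent 0.  Tables print percentages at one decimal.  A stratified 5-fold
cross-validation (`kfold_cv`) checks a pooled training set for
overfitting.  Default held-out triples follow the WESAD subject grouping
({S2,S3,S4} … {S15,S16,S17}, no S12) when the IDs match, else contiguous
triples in ID order.

## Synthetic cohorts

Real wearable IBI data is not bundled, so every stage is validated on a
generator that reproduces the structure the method relies on:

* acute stress shortens the mean IBI and reduces its variability —
  per condition a stationary AR(1) process with marginal mean/sd defaults
  of 0.70/0.04 s (stressed) and 0.85/0.08 s (non-stressed);
* beat-to-beat smoothness — AR(1) coefficient 0.9 (IBIs are strongly
  autocorrelated; any stationary positive-correlation process would do);
* inter-subject heterogeneity — one per-subject mean offset drawn from
  N(0, subject_shift_sd²), default 0.05 s, applied to both conditions, so
  generic models face unseen baselines;
* durations are clipped to the physiologic range (so the filter is a
  no-op on clean synthetic data); an optional contamination fraction
  injects clearly out-of-range beats to exercise the filter.

Everything is reproducible from (seed, subject index).  The generator does
**not** model respiratory sinus arrhythmia, circadian drift, or motion
artifacts, and its two condition cues (level and dispersion) are cleaner
and more transferable across subjects than real stress physiology — so
passing tests demonstrate that the pipeline recovers a planted IBI signal,
not that it attains any particular accuracy on real wearable data.  One
consequence observed in the test suite: because the dispersion cue
transfers across subjects, generic models degrade on unseen synthetic
subjects far more gently than they do on real cohorts.

With the default autocorrelation, the standard deviation of a 28-beat
windowed mean is ≈ 0.68 of the marginal sd, so a midpoint threshold on the
28-beat windowed mean separates the two conditions at ≈ 95%, and at > 99%
once the averaging window (≈ 100 beats) outlives the correlation length;
the test suite asserts both levels.

## Test and script problem sizes

The package's own validation runs at desk scale, sized for a single CPU:

* person-specific signal recovery: 1 subject, 1,500 beats/condition,
  stride 1, 30 epochs — test accuracy ≥ 0.95 required in both domains;
* regime ordering: 9 subjects with subject_shift_sd = 0.08 s, 180
  beats/condition, stride 2, 4 epochs, 3 rotating test triples × 3 seeds —
  mean calibrated ≥ mean generic, mean generic < mean person-specific;
* label-permutation null: validation accuracy must fall inside the 99%
  binomial band around 0.5;
* `scripts/acceptance.py` re-runs the pipeline at slightly smaller sizes
  (1,000 beats person-specific at 20 epochs; the 9-subject cohort for the
  generic/calibrated comparison) and writes the measured quantities as
  JSON.

## Known limitations

* No GPU path; training cost is O(epochs × images × 220 MFLOP) on one
  core (~4 ms per image pass).
* The CNN inventory is a contract: the architecture is validated, not
  configurable beyond feature-map counts obeying the 8-conv plan.
* Binary labels only; baseline/amusement/stress multi-class is out of
  scope, as are BVP peak detection and artifact correction beyond range
  filtering.
* Reported WESAD-style experiments require a locally downloaded WESAD
  tree (`scripts/run_wesad.py`); no real-data results ship with the
  package.
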