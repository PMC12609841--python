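# Methods

`ecgfusion` implements a hybrid classical/deep pipeline for four-class
single-lead ECG rhythm classification (normal sinus `N`, atrial fibrillation
`A`, other rhythm `O`, noisy `~`). Two complementary representations of each
record are fused: a handcrafted vector built from wavelet-scattering
coefficients and five statistical descriptors, and a Morlet scalogram image
consumed by an image backbone. This note records the model, the parameter
choices, and the places where the design was genuinely open.

## Preprocessing

Records are standardized to a fixed length of 8527 samples (truncating keeps
the leading samples, preserving onset alignment; padding appends zeros),
baseline drift is removed with an order-4 high-pass Butterworth filter at
0.5 Hz applied forward–backward (`sosfiltfilt`) so morphology is not
phase-shifted, and amplitudes are min–max scaled to [−1, 1] (a constant
trace maps to zeros rather than dividing by zero). The default sampling
rate is 300 Hz; polyphase resampling is available but off by default.

## Wavelet scattering

Scattering coefficients are the cascade

    S0 x = x * phi
    S1 x(t, l1) = |x * psi_l1| * phi
    S2 x(t, l1, l2) = ||x * psi_l1| * psi_l2| * phi

with analytic Morlet wavelets (a frequency-domain Gaussian minus a
DC-cancelling corrective Gaussian, so every wavelet has exactly zero mean)
and a Gaussian low-pass `phi` whose time-domain standard deviation is T/4
for averaging support T (default: the full record). Convolutions run
circularly on a reflect-padded power-of-two grid via the FFT. Because `phi`
occupies only a few DFT bins when T spans the record, the smoothed outputs
are read off the frame grid directly from those bins — an exact-to-rounding
shortcut that avoids full-length inverse FFTs.

The standard parameters J (octaves), Q (wavelets per octave) and T do not by
themselves pin down a bank layout, so the remaining choices are explicit
configuration with defaults chosen to reproduce the published
(298 frames × 504 channels) feature shape for an 8527-sample record at
J=6, Q=8, T=8527:

* first order: 48 geometric filters `xi_k = 0.35 · 2^(−k/Q)` (relative
  bandwidth `2^(1/Q) − 1`) plus `n_tail = 19` linearly spaced low-frequency
  filters continuing below the ladder, 67 filters in all;
* second order: a dyadic bank of `j2_max = 10` filters, one per octave,
  with the frequency-decreasing admissibility rule that the second wavelet
  must lie in a strictly lower octave than the first (tail filters count as
  octave J), giving 436 admissible paths;
* channels: 1 + 67 + 436 = 504, ordered order-0, order-1 by descending
  center frequency, order-2 lexicographically;
* time: the heavily averaged outputs are sampled on a uniform `n_frames`
  grid (default 298) spanning the record, rather than on a dyadic
  subsampling grid — with T ≈ record length the coefficients vary slowly,
  so the grid density is a presentation choice, exposed as configuration.

Orientation is frames × channels: the five statistical descriptors
concatenate along the channel axis (504 + 5 = 509), which fixes the axis
convention.

## Statistical descriptors

Mean, standard deviation (N−1 denominator), skewness, excess kurtosis and
0.5–40 Hz band power. Skewness and kurtosis deliberately use a mixed
convention — 1/N moment sums of deviations standardized by the N−1 sigma —
matching the defining formulas rather than scipy's biased estimators. Band
power integrates Welch's PSD (Hann window, 1024-sample segments, 50%
overlap; ≥ 3 segments for a 30 s record at 300 Hz) over the band with the
trapezoid rule. Constant inputs get sigma = 0 and zeroed shape statistics,
flagged rather than raised.

## Scalograms

The complex Morlet CWT (center angular frequency omega0 = 6) is evaluated at
32 logarithmically spaced scales in [1, 64] — log spacing matches the
octave-band character of the analysis; the magnitudes are min–max scaled,
bilinearly resized to 128 × 128 and mapped through the viridis colormap to a
three-channel image in [0, 1]. The colormap is a deterministic runtime
lookup; which map produced the original figures is unknowable and immaterial
to the models, which only need a fixed 3-channel encoding.

## Dimensionality reduction and fusion strategies

Per-record vectors are obtained by averaging the combined matrix over frames
(full flattening is available): the reported 509 → k reduction implies PCA
acts on the channel axis, and frame-averaging is the least arbitrary way to
collapse the frame axis given that T-averaging already makes frames nearly
constant. Three strategies feed the heads: plain concatenation; PCA with a
cumulative-explained-variance target (default 95%, minimal k, deterministic
largest-|loading|-positive sign convention, via scikit-learn); and
variance-based selective weighting, implemented as per-column scaling by
normalized sample standard deviations — the natural reading of
"variance-based scaling", documented here as an interpretation. PCA and the
feature standardizer are fit on training folds only and frozen elsewhere.

## Architectures

All networks run on a small numpy reverse-mode autodiff engine written for
this package (`ecgfusion.nn`); its gradients are validated against central
finite differences in the test suite. Backbones (Kaiming-uniform init from
a seeded generator; no pretrained weights anywhere):

* **SimpleCNN** — three conv layers (kernels 5/3/3, filters 8/16/32), ReLU,
  2×2 max-pooling after each, dropout 0.3, a 128-unit fully connected
  embedding. The kernel notation 5×1/3×1 is 1-D; for image input it is
  resolved as square kernels of the leading size, and the literal 1-D
  kernels are kept behind `input_mode="sequence"`.
* **ResNet-18** — 7×7/2 stem, 3×3/2 max-pool, four stages of two basic
  blocks (64/128/256/512), batch normalization throughout, global average
  pooling, dropout 0.5.
* **CNN-Transformer** — conv blocks of 64 and 128 filters (kernel 3),
  pooled to an 8×8 = 64-token grid (pool factor 4 per block keeps the
  attention cost proportionate to the 4-layer encoder), projected to model
  dim 256; 4 pre-norm encoder layers, 8 heads, feed-forward 512, dropout
  0.2; mean-pooled tokens.
* **ViT** — 16×16 patches (64 + class token), 12 pre-norm encoder layers,
  12 heads, hidden 768, feed-forward 3072, dropout 0.1, final layer
  normalization; the class token is the embedding.

The fusion head concatenates the backbone embedding with the handcrafted
vector and applies two fully connected layers (256 then 64 units, ReLU,
dropout 0.3) before the 4-way softmax — the smallest structure that is
still "multi-layer"; sizes are configurable. Dropout is inverted (scaled by
1/(1−p), identity in eval mode); batch norm keeps running statistics for
evaluation.

## Training protocol

Adam (lr 1e−3, weight decay 1e−5), batch size 64, cross-entropy, early
stopping on validation loss with patience 20. Fusion models train in two
stages: stage 1 freezes the backbone and trains the head for up to 50
epochs (lr 1e−3) — since the frozen backbone is run in eval mode its
embeddings are constant and are cached once, making stage 1 cheap; stage 2
fine-tunes jointly for up to 20 epochs with differential learning rates
(backbone 1e−5, head 1e−3). Early stopping applies within each stage and
the best-validation weights are restored per stage; whether the original
recipe stopped per-stage or globally is unstated, and per-stage is the
choice that keeps the two budgets meaningful. Non-fusion models use the
single-stage regime. Handcrafted inputs are standardized to zero mean/unit
variance with training-fold statistics; scalogram pixels stay in [0, 1].

Augmentation (training folds only, enforced structurally: the augmentation
provider is only ever invoked with training-fold indices) combines a smooth
monotone cubic-spline time warp with knot displacements up to 3% of the
record length and additive Gaussian jitter with SD 2% of peak amplitude —
both unstated upstream and chosen as mild, physiologically plausible
defaults.

## Evaluation

Stratified 5-fold CV and leave-one-subject-out (LOSO) splitting; the public
2017 single-lead set has no subject identifiers, so subject = record by
default, with configurable grouping of k records per subject. Metrics:
accuracy; macro F1 and macro precision averaged over classes present in the
test labels (a LOSO fold whose subject lacks a class is not charged for
it); one-vs-rest ROC-AUC per class (NaN when a class is absent) and their
unweighted mean; a row-normalized confusion matrix; and per-sample latency
t_total / N_samples.

## Synthetic generator

Each beat is a sum of five Gaussians (P, Q, R, S, T) on an RR schedule drawn
from a lognormal model parameterized by mean heart rate and RR coefficient
of variation, plus white noise and an optional 0.3 Hz baseline-wander
sinusoid that exercises the high-pass stage. Class presets: `N` rr_cv 0.03
with full morphology; `A` rr_cv 0.25 with the P wave suppressed; `O` rr_cv
0.08 with widened QRS and inverted T; `~` template scaled to 0.1 with noise
SD 0.5. Datasets emulate the benchmark's 5154/771/2557/46 class imbalance
through largest-remainder apportionment (every class guaranteed one
record), draw durations uniformly from 30–60 s, and assign subjects
round-robin so each subject's records span classes.

What the generator does **not** emulate: real inter-subject morphology
variation, electrode artifacts, non-stationary noise, or the subtle
N-versus-O overlap that makes the real task hard. Passing tests therefore
demonstrate that the pipeline is wired correctly and can recover class
structure that is present in its features — not that it reaches any
particular accuracy on real recordings.

## Problem sizes and numerical choices

The end-to-end recovery benchmark uses 200 balanced records in 10 subjects,
three seeded runs, the SimpleCNN fusion variant, stage budgets of 30 and 2
epochs, and float32 scattering — sizes chosen so the full study runs on a
single CPU in minutes while still exercising every pipeline stage.
Scattering is float64 by default (float32 agrees to ~1e−6 relative and
halves the cost). Degenerate inputs are handled by convention rather than
error where a convention is defensible (constant traces, constant
coefficient matrices, single-class test sets); dimension mismatches,
unknown labels, empty signals and Nyquist-violating cutoffs raise
validation errors.

## Known limitations

The numpy engine is CPU-only and unsuited to training the ViT at scale;
the ViT and ResNet paths are exercised at build/forward/Grad-CAM scale in
the tests. Grad-CAM on the ViT uses the patch-embedding grid, an
approximation documented in `interpret`. The reproduction of the published
(298, 504) shape is by documented convention (bank sizes and frame count
are explicit parameters), since the upstream bank layout is not derivable
from J, Q, T alone.
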