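# Methods

This note documents the modelling choices, default parameters and known
limitations behind `multits`. It states how quantities are computed; every
empirical number it mentions is produced by the test suite or
`scripts/acceptance.py`, not asserted here.

## Architectures and layer conventions

All networks operate on channels-last tensors `(batch, time, electrodes,
features)`. Kernel durations are stored in milliseconds and converted with
nearest-integer rounding (ties up, minimum 1 sample), so a spec transfers
across sampling rates with unchanged time scales: 25 ms is 5 samples at
200 Hz and 3 samples at 100 Hz.

The published descriptions of this model family leave bias and
normalisation placement, pooling geometry and head width unstated, while
printing exact trainable-parameter totals. We fixed those free choices,
per family, to the unique configurations whose closed-form counts
reproduce the printed totals, and treat them as the reference
configurations of this package:

* **Common conventions.** Convolutions carry biases; every convolution is
  followed by 2-parameter batch normalisation (scale and shift count as
  trainable; running statistics do not); the classification head is a
  single affine map (1 unit for 2 classes); SE dense layers carry **no**
  biases (the convention of the original squeeze-and-excitation
  networks); input is 62 channels. Weights are Glorot-uniform from a
  recorded seed.
* **MultiT-S** (30,313 parameters): four branches of 24 filters with
  25/50/100/200 ms zero-padded kernels; ReLU and average pooling (1×4)
  after the concatenation, then the temporal SE gate (bottleneck
  ⌊96/16⌋ = 6) and batch norm; depthwise spatial convolution with feature
  multiplier 2 (bias + BN), pointwise to 64 maps (bias + BN), average
  pooling (1×4), spatial SE; flatten (25×64) into the head. In the
  temporal stage the SE gate acts on the ReLU'd, pooled activations and
  batch norm follows the gate: the squeeze then pools non-negative
  activation magnitudes (the reference SE formulation) and the
  normalisation absorbs the average gate scale without erasing the
  per-sample modulation. Parameter counts are unaffected by this
  ordering.
* **Deep ConvNet** (182,497): temporal kernel 20 ms (4 samples), spatial
  convolution over all electrodes, then three conv blocks of 48/96/192
  filters with 30 ms (6-sample) kernels, max pooling (3,3) after each
  block, ELU activations. The 4-sample temporal kernel and 6-sample block
  kernels are forced jointly by the original and reformed totals
  (182,497 and 73,777), two independent constraints; a 5-sample temporal
  kernel (which the published "40 Hz minimum frequency" figure implies)
  cannot reproduce either total. This package follows the counts; Deep
  ConvNet's minimum covered frequency is then 50 Hz.
* **Shallow ConvNet** (101,281): 40 temporal filters of 125 ms
  (25 samples), 40 spatial filters, squaring nonlinearity, average pooling
  (75, stride 15), log.
* **EEGNet** (13,537): 32 temporal filters of 500 ms (100 samples,
  zero-padded), depthwise spatial convolution with multiplier 2 (64 maps),
  separable temporal convolution (80 ms depthwise + pointwise to 64),
  average pooling (1×4) and (1×8), ELU, dropout 0.25 after each pooled
  block.

**Multi-kernel reform.** `multikernelify` replaces the first temporal
convolution of a non-MultiT-S family with the four-branch block at half
the original filter count per branch and halves the spatial stage:
Deep 12×4 branches/12 spatial (73,777), Shallow 20×4/20, EEGNet
16×4 branches with the separable stage halved to 32 pointwise filters
(16,177). For the reformed EEGNet the published "32 spatial filters"
cannot be a depthwise output (the 64 concatenated maps force multiples
of 64); the configuration reproducing 16,177 exactly keeps the depthwise
multiplier at 2, halves the pointwise width to 32, inserts the
multi-kernel block bare (bias, no norm — it is a self-contained
conv+ReLU+pool module) and uses a bias-free pointwise convolution, the
EEGNet reference-code convention. We adopt that reading. The reformed
Shallow ConvNet is the one published total this package cannot reproduce
exactly under any convention consistent with the original Shallow count:
the faithful builder yields 101,441 vs the printed 101,721 (0.3%).

Parameter counts are computed twice — by walking the instantiated weight
arrays and by an independent closed-form per-stage sum — and the equality
of the two routes is asserted for randomized specs in the test suite.

**Minimum frequency covered** is `fs / longest temporal kernel (samples)`:
the slowest oscillation completing one cycle inside the receptive field
(MultiT-S 5 Hz, EEGNet 2 Hz at 200 Hz).

## Training

Adam (step size 1e-3, default moment coefficients), mini-batches of 100,
binary or categorical cross-entropy matching the head. The epoch budget
defaults to 200; the synthetic experiments in the acceptance suite use 30
(they converge long before that at their problem size). Model selection
restores the checkpoint with the best validation accuracy (earliest on
ties); "final epoch" is selectable. Network inputs are z-scored per
channel with statistics from the training fold only. Per-fold training
seeds derive deterministically from the experiment seed and fold index.

## Cross-validation

*Subject-dependent*: within every subject (stratified by class,
switchable), epochs are shuffled and dealt into k=5 folds; each fold's
remaining 80% is split 30/70 into validation and training. *Subject-
independent*: leave-one-subject-out; validation is an unstratified random
30% of the pooled remaining epochs, accepting whatever class imbalance
results. Accuracy aggregation is subject-first: mean, SD and a Student-t
95% CI over per-subject accuracies. The chance level is the majority-class
rate. Folds whose training labels collapse to one class are skipped and
recorded. Leakage guards (pairwise-disjoint train/val/test, each index
tested at most once) are enforced at plan construction.

## Spectral features

Welch PSD with Hann taper, 1 s segments, 50% overlap, density scaling
(configurable). Band powers integrate the density by the trapezoidal rule
over half-open bands theta [4,8), alpha [8,13), beta [13,33),
gamma [33,45) Hz — half-open so adjacent bands never share a bin; the
gamma upper edge is capped at min(45, Nyquist). Features are raw powers
(µV²), channel-major, with an optional log10 switch; whether to normalise
is left to the caller. Near a band edge the trapezoid end-weights can clip
a peak at coarse (1 Hz) resolution; tests that compare bands against a
periodogram oracle therefore use full-length segments (0.5 Hz bins).

## Baselines

KNN with k=21 (Euclidean, clamped with a warning when the training set is
smaller), random forest with 100 trees, and an FCN of two 100-unit
logistic-sigmoid hidden layers trained with Adam for up to 200 epochs,
batch 100 — all via scikit-learn behind one fit/predict contract, wrapped
with a train-fold-only standardiser. An epoch budget of 0 degenerates to
a majority-class predictor.

## Synthetic study conditions

The generator draws each epoch as a sum over the four bands of
`amplitude(class, band) × subject_multiplier(subject, band) ×
topography(band, channel) × sin(2π f t + φ)` with f uniform inside the
band and φ uniform, plus 1/f^1 background noise, scaled to a given RMS.
Defaults, chosen once as a realistic desk-scale stand-in for epoched
emotion-EEG corpora:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 100 Hz | all four bands below Nyquist; compact windows |
| window | 2 s | standard emotion-EEG epoch length |
| channels | 4 | consumer-headband-scale montage, 2 per hemisphere |
| subjects | 4 | enough for subject-first aggregation and LOSO |
| epochs/class/subject | 50 | 200 per class in total |
| noise | 10 µV RMS, 1/f | EEG-like background floor |
| subject jitter | 0.1 (relative SD) | per-subject, per-band gain shifts |
| topography | smooth weights; alpha right-, gamma left-weighted, theta frontal bump | hemispheric asymmetry of affective rhythms |

Preset contrasts: *alpha_contrast* doubles the alpha amplitude (10 vs 5 µV)
in one class — a 4× band-power ratio; *dual_band* splits the contrast
between a ~5 Hz and a ~35 Hz component, separable only by a model that
covers both scales; *null* uses identical amplitude rows.

What the generator does **not** emulate: artifacts (EOG/EMG), non-
stationarity within an epoch, volume-conduction correlation structure
between channels beyond shared oscillations, realistic electrode counts,
or label noise. Passing the synthetic acceptance properties therefore
shows that the implementation can learn multi-scale spectral-spatial
contrasts under subject shift — not that any accuracy level transfers to
real recordings, which remain out of scope.

## Statistics

One-way fixed-effects ANOVA (F clamped at 0 against rounding on identical
groups; p from the F distribution). Dunnett's two-sided many-to-one test
is computed in-package: contrast statistics against the control share the
pooled variance; the adjusted p-value of treatment j is
`P(max_i |T_i| ≥ |t_j|)` under the joint multivariate-t null with
correlations `λ_i λ_j`, `λ_j = sqrt(n_j/(n_j+n_0))`, evaluated by seeded
Monte Carlo (200,000 draws by default) via the one-factor representation;
each p-value is reported with its binomial standard error, and the draw
count and seed are recorded in the report. `scipy.stats.dunnett` serves
as an independent oracle in the tests, never as the implementation.
Paired comparisons use the classical two-sided paired t (df = n−1);
zero-variance differences are rejected as degenerate (the CLI report
flags them and displays p = 1). Accuracies are analysed on the raw
proportion scale.

## Numerical choices and degenerate inputs

float32 is the training dtype (float64 available throughout; gradient
checks run in float64). Temporal convolutions use an im2col/GEMM path
with a memory-guarded fallback to a per-tap loop above ~150 M unrolled
elements. Batch-norm ε is 1e-3 with running-statistics momentum 0.9: the
reference experiments run tens of epochs over a handful of mini-batches,
and a slower momentum leaves inference-mode statistics anchored to their
initialisation, decoupling evaluation accuracy from training accuracy.
The log activation clips at 1e-6. SE bottleneck width is ⌊F/r⌋ with a floor of 1. Pooling that
exhausts the time axis raises a construction error naming the stage.
Epoching discards a trailing partial window; recordings shorter than one
window are an error, as are non-finite samples, single-class training
labels, and epoch stores whose blob fails its length or SHA-256 check.
Affective ratings on the 1–9 valence/arousal scale binarise as
"< 5 → negative", so non-integer ratings are covered.

## Problem sizes

The acceptance suite trains at the generator defaults above (400-epoch
datasets, 30 training epochs, 5 seeds, single evaluation fold per seed;
the null check uses 2 subjects × 30 epochs/class at 200 Hz and 5 training
epochs across all seven models). Parameter-count and statistics checks
are exact or closed-form and run in seconds. These sizes are the
package's reference experiment; every knob scales up through the public
configs.

## Known limitations

* No artifact handling, re-referencing or resampling: inputs are assumed
  preprocessed (the EDF importer converts to µV and validates finiteness
  and a single sampling rate, nothing more).
* Only EDF import is supported (no BDF/GDF); the epoch store is the
  package's own format.
* The evaluation harness reports per-window accuracy; per-trial vote
  aggregation is not implemented.
* No early stopping, learning-rate schedules or augmentation.
* Dunnett p-values are Monte Carlo estimates; with the default 200,000
  draws the standard error near p = 0.05 is ≈ 0.0005.
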