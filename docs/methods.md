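# Methods

This note documents the models and numerical choices behind `pigcall`:
what each stage computes, which parameters matter, what the synthetic
data does and does not emulate, and where the design was genuinely open.

## Signal conditioning

Clips are mono waveforms in [−1, 1].  Short-time analysis uses a 25 ms
frame (1102 samples at the canonical 44.1 kHz), 10 ms hop and a Hamming
window; recordings of single pig calls are quasi-stationary at this
scale, and these are the standard speech-analysis values.  All three
are configuration fields (`frame_ms`, `hop_ms`, `window`), as is the
pre-emphasis coefficient (default 0.97, a first-order high-pass that
flattens the falling glottal source spectrum before spectral fits).

An optional spectral noise gate mirrors the adaptive noise-reduction
presets used when cleaning barn recordings (reduction 20 dB, amount
80%, signal threshold 3 dB).  It estimates a per-frequency noise
ceiling — per-bin *maximum* over the profile frames, so that the
fluctuating magnitudes of stationary noise stay below it — and
attenuates STFT bins within `snr_threshold_db` of that ceiling by
`amount × reduction_db` dB.  Gains never exceed one, so the gate cannot
add energy.  Synthetic clips are clean, so the gate is not part of the
default pipeline.

## The 33-dimensional feature vector

Flattened order: `[STE, FC, FF1..FF4, ΔFF21, ΔFF32, ΔFF43, MFCC1..12,
ΔMFCC1..12]`.

* **Short-time energy.** E(n) = Σ (x·w)² per frame; the clip value is
  the arithmetic mean over frames.  The mean is also used for the
  MFCC/ΔMFCC clip aggregation — a single per-clip value is needed and
  the mean is the least surprising aggregator.
* **Frequency centroid.** Power-weighted mean frequency of the
  one-sided spectrum per frame (FFT length 2048, zero-padded frames),
  averaged over non-silent frames.  The integral's upper limit is taken
  as the Nyquist frequency.  All-zero frames have no defined centroid;
  they are flagged NaN and excluded from the average.
* **Formants.** The clip is resampled to twice the maximum formant
  frequency (default 5500 Hz → 11 kHz working rate), pre-emphasized,
  framed, and an order-14 all-pole model is fitted per frame by the
  autocorrelation (Levinson-Durbin) method.  Complex pole pairs give
  candidate frequencies f = θ·fs/2π and bandwidths b = −ln|r|·fs/π;
  candidates are kept if they lie inside (90 Hz, Nyquist − 90 Hz) with
  bandwidth under 400 Hz.  Frames below 10% of the loudest frame's
  energy are excluded, each remaining frame with at least four stable
  candidates votes, and the clip value is the per-formant median.  If
  fewer than 20% of the energetic frames produce a stable 4-pole set
  the clip is rejected as unstable — this is what plain noise does.
  Order 14 (rather than the textbook 2·formants + 2) is needed because
  the source spectrum's tilt consumes pole pairs; with order 10 the
  fourth resonance of known test signals was biased ~120 Hz low, while
  order 14 recovers all four within ±50 Hz.
* **MFCC.** Pre-emphasis → framing/window → FFT magnitude → 26
  triangular mel filters spanning 0..Nyquist (centers uniform in mel,
  Mel(f) = 2595·log10(1 + f/700)) → log energies floored at 1e−10 →
  orthonormal DCT-II → coefficients 2–13, i.e. 12 values that drop the
  overall-level term.  ΔMFCC is the adjacent-frame difference with a
  zero first row; no regression window is used.

## PCA and the comprehensive evaluation score

Features are z-scored with the n−1 sample standard deviation; the
correlation matrix R = ZᵀZ/(n−1) then has unit diagonal by
construction.  R is eigendecomposed (symmetric solver); eigenvector
signs are fixed so the largest-magnitude entry is positive, making
scores reproducible across linear-algebra backends.  Contribution rates
C_i = λ_i/Σλ accumulate to δ_i, and the smallest k with δ_k ≥ 85% is
retained.  Loadings default to a_i√λ_i — the feature–component
correlation, whose squared column sums equal λ_i — with a `raw` (a_i·λ_i)
convention switch; loadings are descriptive and do not affect scores.

The comprehensive evaluation score weights each retained component's
score by w_i = C_i/δ_k (weights sum to one) and adds them.  It is a
variance-weighted one-dimensional summary of the standardized feature
vector and separates the call classes well enough to be a useful extra
classifier input.

PCA is always fitted on the training split only; validation rows are
transformed with the stored means, standard deviations and
eigenvectors.  Fitting on all data before splitting would leak
validation information and is deliberately not done, even though it is
unclear whether reference workflows always avoided it.

## GA-BP classifier

A fully connected input–10–3 network with logistic sigmoid activations
at both layers.  Inputs are min-max scaled to [0, 1] on training
statistics (sigmoid networks need bounded inputs; the scaler is part of
the stored model).  Classes are ordered grunt=0, squeal=1, cough=2 and
targets are one-hot; prediction is the argmax of the three outputs with
ties broken toward the lowest index.

**Genetic seeding.**  The chromosome is the flattened parameter vector
(weights *and* thresholds: 33·10+10+10·3+3 = 373 genes for the 33-input
variant, 203 for 16, 193 for 15).  Fitness is 1/(1 + training MSE).
Each of 100 generations applies roulette-wheel selection, arithmetic
blend crossover with probability 0.5 per pair, per-gene uniform
mutation in [−1, 1] with probability 0.01, and single-individual
elitism (the incumbent best replaces the current worst if it beats it),
so the best fitness is non-decreasing.  Population size is 50.  The GA
sees only the training split.

**Gradient refinement.**  Training is *incremental* backpropagation:
each epoch visits every sample once in a seeded shuffled order and
applies the per-pattern delta rule for E = ½Σ(o−t)², at learning rate
0.01 for up to 1000 epochs or until the dataset MSE reaches 1e−5.
Batch gradient descent was tried first and rejected: averaging the
gradient over ~650 samples and 3 outputs, through two sigmoid
derivative factors, shrinks the step so much that 1000 epochs at lr
0.01 leave the error essentially unchanged (0.2188 → 0.2182 on the
synthetic study set) and accuracy at chance.  Per-pattern updates are
the classic formulation and converge to >90% validation accuracy under
the same budget.  The epoch-end MSE history is recorded and the
best-epoch parameters are returned, so the reported final error never
exceeds the initial one despite stochastic updates.

The three input variants are `raw33` (all fused features), `pca15`
(retained principal components) and `pca15_plus_score` (components plus
the comprehensive score).  The "15" in the names records the component
count of the reference corpus; the implementation always applies the
85% rule to the training split at hand, so the actual input dimension
is data-driven (the synthetic corpus typically retains ~10 components).

## Evaluation

Confusion matrices have true classes in rows and predictions in
columns.  Accuracy is trace/total — the only multiclass reading
consistent with published three-class tables; precision is column-wise
TP/(TP+FP) (undefined, not zero, for a never-predicted class); recall
is row-wise TP/(TP+FN); macro averages are unweighted class means.
Percentages are rounded to one decimal, half away from zero, to match
conventional report tables.

## Synthetic calls

Each clip is source-filter synthesized: an excitation — impulse train
at the class pitch with ±5% period jitter, spectrally tilted by a leaky
integrator whose corner tracks f0, mixed with mildly low-passed white
noise by the class voicing fraction — filtered through a cascade of
four two-pole resonators.  Per-clip resonance frequencies are drawn
from the class's published formant normal distributions (redrawn until
ascending with ≥150 Hz separation, since closer pairs merge into one
spectral peak and are not resolvable by any all-pole fit); bandwidths
grow from 80 Hz toward 300 Hz with frequency so lower formants
dominate, as in real calls.  Durations are truncated normals (min
0.1 s) with the published class means/sds; coughs get a sharp
attack/exponential-decay burst envelope, the voiced calls a sustained
envelope with raised-cosine edges.

Class settings: grunts f0 = 120 Hz, 90% voiced; squeals f0 = 1 kHz,
60% voiced; coughs f0 = 180 Hz, 15% voiced (noise-dominated bursts).
The amplitude scales (0.137/0.305/0.288 for grunt/squeal/cough) were
calibrated once so the class mean STE values land near the published
0.48/4.14/0.69 with the squeal ≫ cough > grunt ordering; the frequency
centroid ordering squeal > cough > grunt then emerges from the pitch,
tilt and formant settings rather than being imposed.

What the generator does *not* emulate: barn noise and reverberation,
microphone distance effects, overlapping callers, within-call pitch
contours, and the full covariance structure of real features (formants
are drawn independently).  Squeal formant estimates are biased low by
the sparse 1 kHz harmonic sampling of the spectral envelope — the
classic high-pitch limitation of all-pole analysis — which mirrors real
analysis difficulty but means squeal formant *accuracy* is not a test
target; only grunt-like and known-resonance signals are used for
estimator validation.  Consequently, passing tests demonstrate that the
pipeline recovers structure the generator put in, not that field
recordings would classify at the same accuracy.

## Problem sizes and determinism

The study-scale experiment uses the published class counts 291/357/291
(a handful of degenerate draws are screened out by the formant
stability check).  Orderings and preset statistics are checked over 100
clips per class; estimator validation uses 50 clips.  All randomness —
synthesis, splits, GA, SGD shuffling — flows from explicit integer
seeds through NumPy `SeedSequence` spawning, so identical seeds give
byte-identical datasets and identical confusion matrices.

## Known limitations

* Formant estimation degrades for high-pitched calls (see above) and
  assumes at most four resonances below 5.5 kHz.
* The stability screen drops ~1–3% of generated grunts; a production
  system would fall back to a relaxed bandwidth cutoff rather than
  discard clips.
* The GA's contribution at these budgets is modest (it supplies a
  reasonable starting point; most error reduction happens during
  gradient refinement), consistent with its role as an initializer.
* Absolute STE values are unit-free and depend on the frame/window
  choice; only relative class comparisons are meaningful.
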