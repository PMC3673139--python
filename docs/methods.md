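# Methods

## Problem and pipeline

`sportdwt` classifies short sporting-activity events from a single
torso-worn smartphone accelerometer. Seven activities are targeted: four
inertial locomotion states — A1 stationary (0 m/s), A2 walking (1 ± 1 m/s),
A3 jogging (3.5 ± 1.5 m/s), A4 sprinting (5+ m/s) — and three game
activities — A5 hitting the ball, A6 a standing tackle, A7 dribbling. Each
labelled event is a 9-second tri-axial log (units of g) with the activity at
its centre, captured at a fixed device rate (the two modelled handsets
sample at 16 and 25 Hz with 8-bit resolution). The pipeline is:

1. cut a centred analysis window of length L seconds from the log;
2. decompose each axis with a discrete wavelet transform (DWT) to level i;
3. summarise the coefficients into 6(1 + i) dimensionless features;
4. train a classifier (or a fusion of per-activity classifiers);
5. score with macro-averaged F-measure under repeated stratified holdout.

## Windowing

The centre sample is the one nearest the annotated activity centre (index
floor(N/2) for a standard centred log); a window of Nw = round(L × rate)
samples covers indices [c − floor(Nw/2), c + ceil(Nw/2)). This makes
windows of increasing length nested around a fixed centre, so window-length
sweeps change only how much context is included, never where the activity
sits. Logs captured at different device rates are *not* resampled; features
are computed on the raw in-window samples, and their dimensionless form
(below) absorbs most of the rate difference.

## Discrete wavelet transform

The transform is the classic iterated two-channel filter bank: convolve
with a low-pass and a high-pass analysis filter, downsample by two, recurse
on the low-pass branch. After i levels a signal of (padded) length M yields
an approximation vector A_i of M/2^i coefficients and detail vectors D_j of
M/2^j coefficients (j = 1..i).

Numerical choices:

* **Boundary handling** is periodization. Window lengths are rarely dyadic
  (75 samples is the 3-s window at 25 Hz), so each window is first
  mirror-padded symmetrically up to the next multiple of 2^i. Under
  periodization the dyadic length formula above holds exactly, which keeps
  the feature layout independent of the boundary treatment.
* **Alignment.** The analysis step computes
  c[k] = Σ_m f[m] · x[(2k + L/2 − m) mod N] with filter length L; synthesis
  applies the time-reversed reconstruction filters with the same L/2 phase.
  This matches the periodized convention of PyWavelets and MATLAB
  coefficient for coefficient, which the test suite verifies against both a
  scalar brute-force convolution oracle and `pywt.wavedec`.
* **Registry.** Supported mother wavelets are haar, db1–db10, coif1–coif5,
  sym2–sym10, bior1.1–3.9 and rbio1.1–3.9; filter coefficients come from
  the published tables shipped with PyWavelets. Decomposition depth is
  capped at 7 — deeper levels add computation without adding usable
  sub-bands at these sampling rates.
* **Minimum length.** The initial padded length must be at least the
  filter length (explicit error otherwise). At deeper stages the filter is
  periodized modulo the current length; perfect reconstruction still holds
  there (verified to < 1e−8 for every registry wavelet), so deep levels on
  short windows remain well defined.

## Features

For each axis the level-i coefficients are summarised by two blocks:

* **Energy distribution ratios.** With total energy
  E_T = A_iA_iᵀ + Σ_j D_jD_jᵀ, the features are EDR_A = A_iA_iᵀ/E_T and
  EDR_Dj = D_jD_jᵀ/E_T; they are nonnegative and sum to one. A zero-energy
  window (possible only for an all-constant axis) falls back to
  EDR_A = 1, EDR_Dj = 0 with a warning.
* **Normalized coefficient variances.** The population variance (divide by
  n, since deep-level vectors can have a single element) of each of the
  i + 1 coefficient vectors, rescaled to sum to one within the axis; if all
  variances are zero the uniform 1/(i+1) composition is returned. The
  sum-to-one normalization mirrors the EDR construction and keeps the
  block stateless (no training-set statistics inside feature extraction);
  z-scoring against training data was considered and rejected for that
  reason — scale-sensitive classifiers standardize internally instead.

Three axes × two blocks of i + 1 values give 6(1 + i) features — 42 at
level 6. Both blocks are invariant to amplitude scaling of the window,
making them comparable across devices, mounting tightness and subject
build. The feature order (per axis x, y, z: EDR_A, EDR_D1..Di, nvar_A,
nvar_D1..Di) is normative and encoded in the CSV column names
(`x_EDR_D3`, `z_nvar_A`, …).

## Classifiers

Five families sit behind one train/predict contract (`ClassifierSpec` →
`TrainedModel` with `predict_proba`): linear SVM (C = 1) with Platt-style
sigmoid calibration, 1-nearest-neighbour, Gaussian naive Bayes, a
logistic-model-tree approximation, and a one-hidden-layer perceptron with
(features + classes)/2 units (floor 4) trained for up to 500 epochs.
scikit-learn provides the fitted estimators; the logistic model tree has no
ecosystem implementation, so the package ships a documented approximation —
a shallow CART whose leaves hold multinomial-logistic models, falling back
to Laplace-smoothed class proportions in pure or tiny leaves. SVM, kNN and
MLP standardize features with train-set statistics stored in the model;
naive Bayes and the tree consume raw features. Every family is
deterministic given the spec's seed.

**Fusion.** One binary activity-vs-rest model per label; a prediction is
the activity whose model reports the highest positive-class confidence
(probability of the positive class), ties resolving to the lowest activity
index. Confidence comparability across the seven models is why SVM
confidences are calibrated rather than raw margins. For probability-based
scoring the seven confidences are renormalized to a distribution.

## Evaluation protocol

* **Repeated holdout** (default): 10 stratified random 2/3–1/3 splits; the
  averaged report sums confusion matrices and averages per-class P/R/F1,
  macro F and MAE across splits. Splits are stratified — the 30-per-class
  design implies balanced intent — with seeds derived from one master seed.
* **10-fold stratified cross-validation** pools fold predictions into a
  single confusion matrix.
* **Scores.** Per class, P = Tp/(Tp+Fp), R = Tp/(Tp+Fn), F1 = 2PR/(P+R)
  (zero denominators score 0); the macro F-measure is the *unweighted* mean
  of the seven per-class F1 values — the convention under which the
  published worked-example matrices reproduce their printed scores (62.7%,
  65.9%, 0.823). One published matrix (the tuned soccer model) does not
  reproduce its printed 0.799 under any standard aggregation and its rows
  do not all sum to 30, so it is excluded from exact checks.
* **MAE** is the mean absolute difference between predicted class
  probabilities and the one-hot truth over all n × 7 entries; uniform
  predictions give 2(k−1)/k² ≈ 0.2449.
* **Parameter sweep** crosses family × wavelet × level (1–7) × window
  length (default grid {1, 3, 5, 7, 9} s), evaluates each cell by repeated
  holdout, and reports per-axis marginal means plus the best cell.

## Synthetic data

The original study dataset was never deposited, so the package ships a
generator that emulates the capture design: 9-s activity-centred logs,
30 examples per activity per sport (210 logs), a pool of 15 subject
profiles, and both device profiles drawn evenly. The signal model is
deliberately simple, with every parameter exposed:

* locomotion = sinusoids at the stride frequency (walk 1.0 Hz, jog 2.5 Hz,
  sprint 3.5 Hz) plus two harmonics, per-axis amplitudes rising from 0
  (stationary) to ~1.6 g vertical (sprint);
* game activities = damped-oscillation bursts centred at 4.5 s over light
  shuffling; in the outer seconds (> 3 s from centre) jog-like surrounding
  play is added, so windows longer than ~6–7 s mix two activities and
  become genuinely harder — reproducing the qualitative cost of long
  windows in fast-moving play;
* gravity = constant 1 g on the vertical axis rotated by a per-subject
  orientation perturbation (σ = 4°); subjects also scale amplitudes
  (log-normal, σ = 0.15) and jitter stride frequency (σ = 0.06);
* sensor model = Gaussian noise (σ = 0.03 g) and quantization to the 8-bit
  grid over ±4 g.

Sport presets place game-activity signatures on different axes (soccer:
lower-body impacts transmitted vertically; hockey: arm-driven horizontal
motion). The **high-separability** preset gives the three game activities
distinct burst carriers chosen to fall in the same dyadic band at both
device rates (7 Hz → D1, 3.5 Hz → D2, at level 2) and distinct axis
loadings; the **low-separability** preset gives them similar carriers,
energies and a shared axis placement, so A5–A7 blur into one another while
A1–A4 stay distinct — mirroring the qualitative finding that inertial
activities are easy and game activities are the challenge.

What the generator does *not* emulate: biomechanically realistic gait
(no stance/swing asymmetry, no step-to-step variability), real impact
spectra, orientation drift during play, or sensor dropouts. Passing the
end-to-end tests therefore shows the pipeline recovers class structure of
the kind the study describes, not that it would reach any particular
accuracy on real matches.

## Problem sizes used in tests

The test suite and acceptance checks run the full study-scale design where
it matters (210-log datasets, 10-rep holdout for the parameter-recovery
checks) and small grids elsewhere (sweep tests use 1–8 cells with 1–5
reps; CLI round-trips use 6 logs per activity). The whole suite completes
in well under a minute on one CPU.

## Known limitations

* The logistic model tree is an approximation, not the classic stage-wise
  LogitBoost construction; reports name the family
  `logistic_model_tree` but its split/leaf structure is CART + logistic.
* "Confidence" has no single definition across families; calibrated or
  model-native probabilities are used and documented, but other choices
  (raw margins, vote counts) would change fusion behaviour.
* Mixed 16/25 Hz capture shifts which physical frequencies land in which
  dyadic band; the dimensionless features reduce but do not remove this
  effect, and no resampling step is applied.
* Simulator realism cannot be validated against the original signals (no
  amplitude or spectral statistics were published); only qualitative
  orderings (sprint > walk energy, game-activity confusability) are
  testable.
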