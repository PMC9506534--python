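# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `pulsebp`.

## The beat model

A single PPG pulse is modelled as the sum of a Gamma kernel (systolic
forward wave) and a Gaussian kernel (reflected/diastolic wave):

```
y(t; θ) = a₁ (t/μ₁)^(α₁−1) e^(−β₁ (t−μ₁))  +  a₂ exp(−(t − μ₂)²/2σ₂²),
θ = (a₁, α₁, β₁, a₂, μ₂, σ₂),   μ₁ = (α₁ − 1)/β₁.
```

The Gamma term is the Gamma density rescaled so that its **peak value is
`a₁`** (amplitude parameterization).  This choice resolves the scale
ambiguity of the raw density form: the decomposition features P1/P2 are
described as kernel *amplitudes*, and under this parameterization they
are literally `a₁` and `a₂`.  All times inside θ are in seconds, so the
fitted parameters (and the features derived from them) are invariant to
the sampling frequency of the source recording.

Two physiological ordering constraints are enforced as hard constraints:
the systolic wave is larger (`a₁ > a₂`) and earlier (`μ₁ < μ₂`) than the
reflected wave.

### Fitting

Fitting is bound-constrained nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective).  The ordering
constraints hold *by construction* through the reparameterization
`a₂ = a₁·u` with `u ∈ (0, 1)` and `μ₂ = μ₁ + δ` with `δ > 0`; no fitted
beat can violate them, which the acceptance checks confirm over every
synthetic run.

Initialization is data driven: the Gamma mode starts at the beat's
global maximum, the Gaussian center at the largest local maximum after
it (or 40% of the remaining duration past the peak when none exists),
amplitudes from the corresponding sample values, and σ₂ at 15% of the
beat duration.  Optimizer budget: 500 residual evaluations, tolerances
1e-10; when the budget is hit the best-so-far parameters are returned
with `converged=False`.  Bounds: `a₁ ∈ [1e-3, 2]`, `α₁ ∈ [1.2, 60]`,
`β₁ ∈ [0.5, 300]`, `u ∈ [1e-3, 0.999]`, `δ ∈ [1e-3, 3]`,
`σ₂ ∈ [0.005, 1]` (seconds).  On noiseless synthetic beats the fit
recovers the generating parameters to ~1e-11 relative error; at additive
noise sd 0.02 (2% of the normalized amplitude) the worst per-parameter
median relative error is ~2–3%.

### Widths

The feature set needs a "width" per kernel.  Both are defined as **full
width at half maximum**: closed-form `2√(2 ln 2)·σ₂` for the Gaussian,
numeric root-finding on the log-kernel for the Gamma.  FWHM is the
standard width in pulse-wave analysis; other definitions (e.g. standard
deviation widths) would be monotone transforms for the Gaussian but not
for the skewed Gamma.

## Preprocessing choices

* **Bandpass** 0.4–12 Hz, 5th-order Butterworth, applied
  forward–backward (`sosfiltfilt`) so beat landmarks keep their timing.
  Requires `fs > 24 Hz`.
* **Beat detection**: local maxima of the first difference of the
  filtered signal (steepest ascent), spaced at least a refractory period
  apart, accepted when exceeding an adaptive threshold (default 0.3×
  the running median of the last 10 accepted slope maxima, seeded with
  the 90th percentile of candidate slopes).  The refractory default is
  0.5 s: beats with a strong reflected wave carry a *secondary* slope
  maximum ~0.3–0.45 s after the systolic upstroke, and a shorter
  refractory period would double-detect such beats.  Both constants are
  config-exposed; 0.5 s caps the detectable heart rate at 120 bpm, which
  suits resting and anesthesia recordings but not exercise data.
* **Segmentation**: onset/offset are the signal minima in windows on
  each side of the detection point.  The default window spans the full
  interval to the neighbouring detection: with realistic inter-beat
  intervals the diastolic minimum sits close to the *next* beat's
  upstroke, and short fixed windows systematically miss it.  The first
  and last detections of a record lack a neighbour and are dropped.
  The minima are searched on the **raw** signal: the zero-phase bandpass
  shifts minima in flat diastolic segments by up to ~40 ms (high-pass
  undershoot), while raw minima coincide with the true beat boundaries.
* **Detrend + normalize**: each beat has the *baseline* (secant through
  the means of its first and last 3 samples) subtracted, then is
  rescaled to exactly [0, 1].  A whole-beat least-squares detrend was
  rejected: the regression line over an asymmetric pulse has a
  substantial slope driven by the pulse shape itself, and subtracting it
  moves every beat outside the kernel model class (observed noiseless
  fit residuals up to RSS ≈ 0.45 with badly biased parameters).  The
  baseline secant removes within-beat drift — the quantity detrending
  exists to remove — while leaving kernel-expressible beats exactly
  fittable.  A `least_squares` mode is kept for comparison.  The
  operation is idempotent.
* **Response assignment**: nearest reference BP sample in time to the
  beat's detection point; records carrying a single cuff value assign it
  to every beat.

## Features

Per beat: P1, P2, T1, T2, W1, W2 from the fitted kernels; b/a, SD, kurt,
skew and PW from the fitted reconstruction (the fit acts as a denoiser,
which matters most for the twice-differentiated b/a); Freq0–Freq3 from
the original normalized beat.

* Moments use the population (1/N) convention; kurtosis is non-excess
  (Gaussian → 3).
* PW is the width of the reconstruction at 50% of its amplitude range,
  in seconds, with linear interpolation at the crossings.
* b/a: the second difference scaled by fs²; the a wave is the first
  prominent maximum (prominence ≥ 2% of the second-derivative range) on
  the systolic rising edge, the b wave the first minimum after it.  For
  a pure Gaussian pulse this yields the closed form −e^{3/2}/2 ≈ −2.2408,
  which the tests verify to 1%.
* Frequency features: the beat is tiled 10×, making it exactly periodic
  with period equal to its duration; Freq0 is the largest non-DC
  spectral peak and Freq1–3 the local maxima nearest 2–4× Freq0
  (accepted within ±0.5·Freq0, config-exposed).  These are peak
  *frequencies* in Hz, not magnitudes — for a strictly periodic tiled
  beat the k-th harmonic sits at (k+1)/T, so on clean data the features
  are nearly collinear with Freq0; they are retained for fidelity to the
  15-feature set.  (The feature family is labelled Freq0–Freq3 here;
  discussions of such feature sets sometimes number the harmonics
   1-based instead, so "freq2/freq4" elsewhere may denote Freq1/Freq3 in
  this numbering.)
* Missing sub-features propagate as NaN plus an explicit missing flag;
  rows with any missing feature are excluded from training/testing with
  counts logged, never silently zero-filled.

## Estimation

* **Split**: strict mode assigns whole subjects (per source) 80/20,
  `floor` rounding with at least one unit on each side; co-assignment
  groups (e.g. two sessions of one person) form indivisible units.
  Pooled mode splits beats at random and exists to quantify the
  subject-leakage effect: on a synthetic cohort with 8 mmHg
  subject-level BP offsets, pooled test MAE is roughly half the strict
  MAE — the separation effect that makes pooled results incomparable to
  subject-separated ones.
* **Weights**: rows above half the maximum training response get weight
  0.375 (others 1.0), countering the right tail of the BP distribution.
  The threshold is computed on the pooled training set (config allows
  per-source).  Note the rule's boundary behaviour: if all responses are
  equal, every positive response exceeds half of itself, so all rows get
  0.375 — harmless since only relative weights matter.
* **Regressor**: xgboost at library defaults, no tuning, fixed seed,
  `n_jobs=1`; hyperparameters recorded verbatim in the model manifest.
  Package-internal predictions re-evaluate the parsed trees in float64
  (routing decisions in float32, matching xgboost): this makes the
  Shapley local-accuracy identity exact to machine precision instead of
  xgboost's ~1e-4 float32 accumulation error.  Agreement with xgboost's
  own evaluator is asserted to 1e-3.
* **Median post-filter**: centered 11-beat running median with
  edge-truncated windows, applied per record to predictions *and*
  continuous references before any metric; single-cuff sources are not
  filtered; series shorter than the kernel pass through unchanged.
  Filtering precedes all metric stratification.
* **Metrics**: MAE, ME = mean(true − estimated) (negative ME ⇒
  overestimation), SDE = population sd of the error, Pearson r
  (undefined and reported as null under zero variance).

## The synthetic cohort

Defaults (the study conditions of the test suite and acceptance script):
50 subjects × 100 beats at 125 Hz; additive white noise sd 0.01 and a
0.05-amplitude 0.2 Hz sinusoidal drift (below the high-pass corner, so
the bandpass removes it — a built-in filter test); inter-beat intervals
0.9 ± 0.05 s.

* **Morphology sampling**: kernel parameters are drawn from uniform
  ranges (`a₁ ∈ [0.75, 1]`, `α₁ ∈ [4, 9]`, `β₁ ∈ [15, 35]`,
  `a₂ ∈ [0.25, 0.6]`, `μ₂ ∈ [0.45, 0.62]` s, `σ₂ ∈ [0.10, 0.16]` s),
  with rejection of draws violating the ordering constraints, so 100% of
  emitted parameter sets are valid.  Within a record the parameters
  follow a reflected random walk (step sd 0.08 in normalized range
  units) rather than i.i.d. draws: real morphology — and with it BP —
  drifts over tens of beats, and an i.i.d. cohort would let the 11-beat
  median filter destroy the very signal it is meant to clean.
* **Beat duration** is clipped to 1.8–2.5 σ₂ past the Gaussian center so
  the diastolic tail is still decaying (but nearly returned to baseline)
  at the boundary.  Both alternatives are pathological: a dead-flat tail
  makes the boundary minimum ill-defined under noise, and a tail cut off
  high leaves a baseline jump between beats.
* **Records** carry one unannotated run-in and run-out beat so that
  every annotated beat has a neighbouring detection on both sides and
  survives segmentation; at zero noise the segmented beat count equals
  the annotation count exactly.
* **BP coupling** (default `skew_ba`):
  `SBP = 120 − 25·(skew − 0.36) + 45·(b/a + 0.85) + N(0, 2 mmHg)`,
  with the references at the cohort means of the two features, giving a
  realistic SBP distribution (≈ 120 ± 12 mmHg, range ~90–150).  The
  coefficients give each generative feature a comparable, learnable
  share of the variance.  An optional per-subject offset (sd in mmHg)
  creates the between-subject variation that makes pooled splits
  optimistic.  Ground-truth *waveform* features are computed on the
  canonically detrended/normalized clean beat — the deterministic
  transform any noiseless pipeline run applies — so recovery tests
  measure noise robustness, not transform mismatch.  Kernel-landmark
  ground truths are the generative parameters themselves.

What the generator does **not** emulate: sensor optics and contact
pressure, motion artifacts, arrhythmias and ectopic beats, realistic
hemodynamic coupling between pressure and morphology.  Passing tests
therefore demonstrate the pipeline's internal correctness and its
robustness to additive noise, drift and segmentation jitter — not
clinical accuracy on real recordings.

## Shapley interpretation

The value function is **interventional**: the payoff of a coalition S
for sample x is the model prediction averaged over a background set with
the features in S fixed to x's values.  The background is the training
feature matrix, subsampled (seeded) to at most a configurable size
(default 200).  The interventional form was chosen because it is the one
the brute-force coalition enumeration defines, so the tree-exact
algorithm and the oracle are comparable without approximation; the two
agree to ~1e-13 on shared backgrounds.

For tree ensembles the attribution is computed exactly per leaf: for a
(sample, background-row) pair, a leaf contributes only if no path
feature fails for both; the features where only the sample passes (count
a) receive `+v·(a−1)!·b!/(a+b)!` and those where only the background row
passes (count b) receive `−v·a!·(b−1)!/(a+b)!`, averaged over the
background.  Local accuracy (base value + row sum = prediction) holds by
construction and is verified to 1e-6 over every test sample.

Reports: global importance is the per-feature mean |ϕ| sorted descending
(ties broken by feature name); beeswarm exports carry the top-k features
(default 9) plus a per-sample "sum of remaining" aggregate; dependence
exports trim the feature's 1st/99th percentiles by default and report
the Spearman rank correlation; subset reports stratify by |error| > 2·MAE,
|error| < MAE/2, prediction below 0.8× / above 1.2× the mean prediction
(mean over the full test set, computed before stratification; errors
taken as absolute values), and by source.  Empty strata produce flagged
`n=0` reports.  Pairwise interaction attributions are out of scope.

## Problem sizes

The test suite and acceptance script run at desk scale on one CPU:
the end-to-end cohort is 50×100 beats (≈45 s including ~5000 kernel
fits and full-test-set attributions), parameter recovery uses 2×200
beats, oracle equivalence 50 samples × 2⁶ coalitions × 50 background
rows, and split integrity 100 seeds.  Accuracy-on-real-data figures
require the original clinical recordings and are outside what synthetic
data can certify.

## Known limitations

* The beat detector assumes resting-range heart rates (≤ 120 bpm with
  the default refractory period).
* b/a is the least stable feature: it is a second-derivative quantity,
  and small reconstruction errors on the rising edge move the a/b
  extrema; its truth-recovery correlation degrades fastest with noise.
* The Gamma/Gaussian model covers single-notch beats; beats with
  multiple reflections or severe artifacts fit poorly (high `fit_cost`,
  `converged=False`) and should be screened by the caller.
* Single-channel PPG only; no multi-wavelength or contact-pressure
  inputs, no cuff-based calibration schemes.
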