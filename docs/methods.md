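# Methods

This note documents the models, conventions and numerical choices behind
`eegsef`: a pipeline that extracts transient spectral-event features
(SEF) and averaged power features (APF) from resting-state frontal EEG
and predicts continuous antidepressant treatment response (percentage
change in HAM-D) with a permutation-tested elastic net. Because suitable
clinical EEG corpora are access-restricted, the package ships a
synthetic-cohort generator with exportable ground truth; every empirical
statement below is one the test-suite or `scripts/acceptance.py`
computes.

## Signal model and preprocessing

Input is continuous multichannel EEG (microvolts) on the seven frontal
10-20 channels (Fp1, Fp2, Fz, F4, F3, F7, F8). Cleaning is:

1. zero-phase 4th-order Butterworth band-pass, 0.5–50 Hz
   (`sosfiltfilt`; zero phase preserves burst timing, on which FWHM
   durations depend);
2. common-average re-referencing;
3. tiling into non-overlapping 5-s epochs, dropping epochs whose peak
   absolute amplitude exceeds `reject.amp_uv` (default 150 µV) on any
   channel or whose per-channel sample kurtosis is a >5-sigma outlier
   across epochs.

ICA-based ocular-artifact removal and correlation-based channel
rejection are deliberately not implemented: they are non-deterministic,
need human or classifier labelling, and the synthetic validation surface
contains no ocular artifacts. Real-data users should pre-clean
accordingly; the amplitude/kurtosis rules are a documented
simplification. Rejection operates at the 5-s epoch level only.

## Time–frequency decomposition

Each epoch is decomposed with complex Morlet wavelets on a 1-Hz grid
from 1 to 30 Hz with a fixed 7 cycles at every frequency (the
spectral-event-analysis convention; the cycle count is the dominant
time–frequency resolution trade-off and is exposed in the config).
Wavelets are applied in the frequency domain: each wavelet's spectrum is
a Gaussian centred on its carrier f with sigma_f = f/7, sampled on the
padded DFT grid (pad ≥ 2x the epoch so wrap-around tails are negligible
above ~2 Hz), and the product spectrum is folded modulo N/decim before
the inverse FFT. The fold identity `ifft(fold(Y, d))[m] = ifft(Y)[m d]/d`
makes the decimated output an exact subsampling of the full-rate
transform (up to float32 rounding); the pipeline default is `decim = 5`
(4 ms → 20 ms time grid), chosen because event durations are
wavelet-blurred to ≳100 ms so a 20 ms grid with interpolated
half-max crossings loses nothing measurable while cutting compute ~3x.
Amplitudes are scaled so a stationary unit-RMS sinusoid reads power 1.
At 1–2 Hz a 7-cycle wavelet outlasts the 5-s epoch; those rows are
computed against the zero-padded epoch and flagged in a log warning.
An independent cross-check in the test-suite verifies agreement with
`mne.time_frequency.tfr_array_morlet` up to a per-frequency constant.

## Factor-of-median normalisation and event detection

Per channel, every frequency row of the power TFR is divided by its
median over *all* kept epochs and time points, relating each point to
the typical resting power of the whole recording at that frequency. An
*event* is a strict 8-connected local maximum of this FOM array within
an epoch with value ≥ 6 (the threshold multiplier is configurable; the
threshold-validation routine reproduces the area-vs-mean-power
correlation analysis over cutoffs 2/4/6). Plateau ties keep the first
point in (time, frequency) scan order. Duration is the FWHM along the
peak's frequency row, span the FWHM along its time column; half-max
crossings are linearly interpolated, searches stop at grid edges and
edge-limited events are flagged `truncated` but still counted. Events
are assigned to delta/theta (2–5 Hz), alpha (6–14 Hz) or beta
(15–29 Hz) by peak frequency only; events are never split at band
edges.

Subject-level SEF are, per channel and band: rate (events per 5-s
epoch) and the means of event FOM power, duration (ms) and span (Hz);
zero-event cells are missing and imputed downstream. 7 channels x 3
bands x 4 features = 84 SEF per subject.

**A property worth knowing:** for any stationary Gaussian background the
FOM has an exponential tail, so P(FOM > 6) = 2⁻⁶ ≈ 1.5 % per
time–frequency pixel. On this geometry that yields ≈ 4 suprathreshold
beta-band maxima per 5-s epoch from background alone — regardless of
spectral shaping, since FOM is per-frequency scale-invariant. Detected
rates therefore sit on an irreducible noise floor, and event-mean
features are a mixture of burst-driven and background-driven events.
The detector itself is accurate: matched against injected ground truth,
≥ 90 % of resolvable bursts (≥ 100 ms, not clipped by an epoch edge)
are found with durations matching the wavelet-blur prediction. The
validation module reports both the aggregate rates (floor included) and
the matched recovery.

Durations of detected bursts are not the injected durations: the
wavelet's Gaussian temporal kernel (sigma_t = 7/(2 pi f), ≈ 56 ms at
20 Hz) blurs the burst envelope before squaring.
`expected_blurred_duration_ms` computes the predicted measured duration
of a Hann burst numerically and is the oracle for duration-recovery
checks. A side effect of the blur is that longer bursts lose less peak
amplitude, so a subject with longer bursts also shows higher event FOM
power — duration effects partially transduce into power effects.

## Averaged power features

From the same Morlet TFR (one spectral estimator for everything):
absolute band power (integral of the time-averaged spectrum over the
band's 1-Hz bins; "overall" integrates 1–30 Hz), relative power
(band/overall, in (0, 1], summing over the three bands to < 1),
cordance (per band, the mean of z-scored absolute and z-scored relative
power, z-scored across the subject's channels so a single subject is
computable in isolation; an across-subject variant exists), and
power-envelope connectivity (PEC): per band and ordered channel pair,
band-pass + analytic signal per epoch, pointwise removal of the
component of one channel's analytic signal collinear with the other's
(the residual envelope is |Im(a_y conj(a_x))/|a_x||), Pearson
correlation of envelopes over concatenated epochs (per-epoch averaging
available), and averaging of the two directions. 28 + 21 + 21 + 63 =
133 APF per subject.

## Prediction model

Feature matrix: the selected block(s) (SEF 84, APF 133, or both) plus
pre-treatment HAM-D — 85 columns for SEF-only. Outcome: percentage
change, 100·(post − pre)/pre, negative for improvement; responder =
decrease ≥ 50 % (pct ≤ −50).

The estimator (`ElasticNetResponseModel`, scikit-learn protocol) wraps
`StandardScaler → KNNImputer(k=2) → ElasticNet`. Z-scoring precedes
imputation so neighbour distances are scale-free. The outer split is
2/3–1/3 stratified by responder flag; hyperparameters (alpha ∈
{0.1, 0.3, 1, 3, 10}, L1 ratio ∈ {.1, .5, .9}, intercept ∈ {on, off})
are selected by stratified 3-fold CV on the training split maximizing
negative RMSE, with degenerate (single-class) fold draws reshuffled.
Zero-variance training columns are dropped with a warning and recorded.
The in-sample r² of predicted vs true on the training split is reported
for comparability with published models, documented as an optimistic
metric.

Permutation inference (one-sided, p = (1 + #{null ≥ observed})/(1 + N)):
the training-phase p refits the selected elastic net per CV fold on
outcome-shuffled data, averaging fold scores — the semantics of
scikit-learn's `permutation_test_score`, verified exactly in a test.
Because the X-side preprocessing is outcome-independent, it is
precomputed once per fold and only the elastic net is refit per
permutation (an exact optimisation). The test-phase p shuffles held-out
outcomes against the frozen model's predictions; the same frozen
mechanism implements cross-arm application (a model fit on one arm,
including its normalisation and imputation, applied unchanged to
another). The train-phase procedure inherits the selection-bias
anticonservatism of testing after hyperparameter search (selection is
not repeated inside the null); the test-phase p is exactly calibrated
by construction and is the package's primary significance statement.

Post-hoc: permutation feature importance (mean negative-RMSE drop over
column shuffles; top-5 and |importance| > 1.5 sets), channel-level
Pearson correlations of selected features with the outcome corrected by
Bonferroni (Holm available) across exactly the tested features,
one-sided two-sample t-tests (Student pooled by default, Welch
available) for responder/remitter/control contrasts, and greedy
nearest-age matching (control order seed-randomized) for the
patient–control comparison.

## Synthetic cohorts

Each subject's recording is an independent 1/f Gaussian background
(spectral shaping of white noise, exponent 1.0, 5 µV RMS, optional
alpha bump) plus, per channel, epoch and burst class, a Poisson number
of Hann-windowed sinusoids: delta/theta class 3.5 Hz (rate 0.3/epoch,
350 ± 100 ms), alpha 10 Hz (0.5, 200 ± 60 ms), beta 20 Hz (0.5,
150 ± 50 ms), all at 10x background RMS, lognormal durations, uniform
onsets, clipped at epoch edges (a burst longer than an epoch is
truncated with a warning). Defaults: 7 channels, 71 five-second epochs,
250 Hz. Every (channel, burst-class) cell of every subject carries an
independent lognormal random effect (sigma 0.30) on its duration mean —
sized so subject-level beta duration means span roughly 100–300 ms —
and the outcome is

    pct_change = intercept + effect_slope * z + Normal(0, noise_sd)

with z the standardized random effect of the designated cell (default
Fp1 x beta x duration), intercept −45, slope −10 and noise 15.3 (so the
planted outcome R² is ≈ 0.3). HAM-D pre is uniform-integer 18–30
(plausible moderate-to-severe trial severities; the value affects no
validation property), post is derived by rounding, ages are N(39, 13²)
clipped to 18–70. The sign convention: slope −10 means longer durations
accompany more negative (greater) symptom decrease on the signed
percentage scale — channel-level duration–outcome correlations are
negative. Everything is deterministic given (seed, subject index);
recordings are bit-identical across runs, and injected-burst ground
truth is exported for matching.

What the generator does **not** emulate: volume conduction and realistic
channel covariance, ocular/muscle artifacts, non-Gaussian heavy-tailed
background, non-stationary arousal drifts, site/hardware effects. A
green validation therefore shows the pipeline recovers planted effects
under idealised noise, not that equivalent effects are recoverable from
real clinical EEG.

## Validation studies and problem sizes

The acceptance suite (tests/test_acceptance.py) and the reproduction
script run these studies end to end. Monte-Carlo sizes are the
package's choices, balancing statistical resolution against a
single-CPU run: permutation calibration uses 20 independently simulated
null cohorts of n = 40 subjects x 30 epochs (the calibration property
does not involve the epoch count) with 10 independent outcome redraws
each (200 replicates; valid because under the null the outcome is
independent of the EEG, so p-values at fixed features are i.i.d. across
redraws) at 199 permutations; planted-effect recovery uses 20 cohorts
of n = 82 at the full 71 epochs;
placebo specificity applies each frozen model to an independent null
arm of n = 24; the reproduction script runs a 10 x 10 calibration and
8 recovery replicates. Known red results under these conditions — the
aggregate detected rate exceeding the injected rate by the background
floor, and the planted duration feature reaching top-5 importance only
rarely because the effect expresses more strongly through beta power —
are measured and reported as-is; the mechanisms are described above.

## Numerical notes and limitations

* float32 FFT path in the TFR (validated against float64 full-rate
  computation); FOM, features and statistics in float64.
* FWHM: linear interpolation, edge-truncation flagging; equality with a
  brute-force crossing-scan oracle to ≤ 1e-9 relative is enforced.
* Gain invariance of SEF is exact for power-of-two gains (pure exponent
  shifts) and to ~1e-9 otherwise; the absolute-µV amplitude-rejection
  rule is intentionally not gain-invariant.
* EDF is read via mne; recordings are written as .npy + JSON sidecar
  (no EDF writer dependency).
* The elastic-net grid is a compact bracket, not a replication of any
  particular study's unpublished grid; published clinical effect sizes
  are not reproducible from synthetic data and are not targets.
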