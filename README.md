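# eegsef

Transient spectral-event features from resting-state EEG, and
permutation-tested elastic-net prediction of antidepressant treatment
response.

## The problem

Resting-state EEG biomarkers of antidepressant response have mostly been
built from *averaged* power features (APF): band power, relative power,
cordance, power-envelope connectivity. But in non-averaged data, band
power arrives as transient, high-power *spectral events* — bursts
lasting a few hundred milliseconds whose rate, amplitude, duration and
frequency span carry information the averages blur away. This package
implements an end-to-end pipeline for clinical neurophysiology
researchers who want to test whether such spectral event features (SEF)
from frontal channels predict continuous symptom change after treatment:

* **preprocess** — 0.5–50 Hz zero-phase band-pass, common-average
  reference, amplitude/kurtosis rejection, 5-s epochs;
* **tfr / events** — Morlet time–frequency power (1–30 Hz, 7 cycles),
  factor-of-median (FOM) normalisation per frequency, event detection as
  suprathreshold (≥ 6× median) local TFR maxima, FWHM duration and
  frequency span by interpolated half-max crossings, per-subject
  averages per channel and band (delta/theta 2–5, alpha 6–14, beta
  15–29 Hz);
* **power** — APF from the same spectral estimator: absolute/relative
  band power, cordance, orthogonalized power-envelope connectivity;
* **predict** — a scikit-learn estimator wrapping z-scoring, k=2 KNN
  imputation and an elastic net, with stratified 2/3–1/3 split,
  stratified 3-fold CV grid search (alpha, L1 ratio, intercept),
  held-out evaluation, one-sided permutation tests
  (p = (1 + #{null ≥ obs})/(1 + N)) and frozen cross-arm application;
* **posthoc** — permutation feature importance, Bonferroni/Holm-corrected
  channel-level correlations, one-sided t-tests for responder/remitter/
  control contrasts, greedy age matching;
* **synthetic** — a cohort generator (1/f background + Hann-windowed
  Poisson bursts with lognormal durations, subject-level random effects,
  outcome linearly coupled to a chosen feature) with exportable burst
  ground truth, standing in for access-restricted clinical recordings.

The outcome convention is percentage change in HAM-D,
100·(post − pre)/pre — negative means improvement; a responder has a
decrease of at least 50 %.

## Worked example

Run the full pipeline on a synthetic sertraline-like cohort (82
subjects, 71 five-second epochs, planted negative coupling between Fp1
beta burst duration and symptom change):

```bash
eegsef run-all --out demo --seed 7
```

or equivalently in Python:

```python
from eegsef import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(n_subjects=82, n_perm=199, seed=7), "demo")
```

A run with the configuration above printed:

```
hyperparameters: {'alpha': 10.0, 'fit_intercept': True, 'l1_ratio': 0.5}
train negRMSE -14.14  test negRMSE -17.71
permutation p (train/test): 0.170 / 0.005
top importance:  Fp1_beta_power  0.122  (rank 1)
channel-level:   Fp1_beta_power  r = -0.485  p_corrected = 4e-06
```

Reading this: the grid search selected a strongly regularized model that
kept essentially one feature, Fp1 beta event power. Its held-out
predictions beat outcome-shuffled nulls (test-phase p = 0.005), and the
feature correlates with symptom change at the channel level
(r = −0.485: subjects with higher pre-treatment Fp1 beta event power
improved more). The effect was *planted* on Fp1 beta duration — the
wavelet's temporal blur makes longer bursts also read as
higher-powered, so the model legitimately finds the effect through the
power feature; the duration feature itself is diluted by the detector's
background-event floor (see `docs/methods.md`). `demo/` also contains
the per-subject SEF table, the event TSV, the burst ground truth,
predictions and a checksum manifest; re-running with the same config
reproduces it bit-for-bit.

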