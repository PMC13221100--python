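"""Synthetic resting-state EEG cohorts with known burst statistics and a
planted feature-outcome relationship.

Each recording is a 1/f Gaussian background plus transient band-limited
bursts: per 5-s epoch and burst class, a Poisson number of Hann-windowed
sinusoids with lognormal durations and uniform-random onsets. Every
subject carries an independent lognormal random effect on the duration
mean of each (channel, burst-class) cell, so between-subject variability
exists everywhere; the clinical outcome (percentage change in HAM-D) is
linearly coupled to the subject's true duration of one chosen cell (the
*effect feature*, default Fp1 beta duration with a negative slope) plus
Gaussian noise.

Ground truth for every injected burst (onset, duration, frequency,
amplitude) is returned alongside the signals for detector validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FRONTAL_CHANNELS, Recording

log = logging.getLogger(__name__)


@dataclass
class BurstSpec:
    """One class of transient bursts injected into every channel."""

    band_low_hz: float
    band_high_hz: float
    rate_per_epoch: float
    duration_ms_mean: float
    duration_ms_sd: float
    center_freq_hz: float
    amplitude_rel: float

    def __post_init__(self) -> None:
        if not self.band_low_hz < self.band_high_hz:
            raise ValueError("band_low_hz must be < band_high_hz")
        if self.rate_per_epoch < 0:
            raise ValueError("rate_per_epoch must be >= 0")
        if self.duration_ms_mean <= 0:
            raise ValueError("duration_ms_mean must be > 0")
        if self.amplitude_rel <= 0:
            raise ValueError("amplitude_rel must be > 0")


def default_bursts():
    """Burst classes mirroring the delta/theta, alpha and beta bands."""
    return (
        BurstSpec(2.0, 5.0, rate_per_epoch=0.3, duration_ms_mean=350.0,
                  duration_ms_sd=100.0, center_freq_hz=3.5, amplitude_rel=10.0),
        BurstSpec(6.0, 14.0, rate_per_epoch=0.5, duration_ms_mean=200.0,
                  duration_ms_sd=60.0, center_freq_hz=10.0, amplitude_rel=10.0),
        BurstSpec(15.0, 29.0, rate_per_epoch=0.5, duration_ms_mean=150.0,
                  duration_ms_sd=50.0, center_freq_hz=20.0, amplitude_rel=10.0),
    )


@dataclass
class CohortSpec:
    """Cohort geometry, burst statistics and the planted outcome model."""

    n_subjects: int = 82
    channel_labels: tuple = FRONTAL_CHANNELS
    n_epochs: int = 71
    epoch_s: float = 5.0
    fs_hz: float = 250.0
    background_exponent: float = 1.0
    background_rms_uv: float = 5.0
    alpha_bump_gain: float = 0.0
    bursts: tuple = field(default_factory=default_bursts)
    #: (channel, burst-class index, feature) cell driving the outcome
    effect_channel: str = "Fp1"
    effect_burst: int = 2  # index into `bursts`; default = beta class
    effect_slope: float = -10.0
    outcome_intercept: float = -45.0
    noise_sd: float = 15.3
    subject_duration_sigma: float = 0.30
    hamd_pre_range: tuple = (18, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        n = self.epoch_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_s x fs_hz must be an integer sample count")
        if self.effect_channel not in self.channel_labels:
            raise ValueError("effect_channel not in channel_labels")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_s * self.fs_hz))


def _lognormal_params(mean: float, sd: float):
    """(mu, sigma) of the underlying normal matching the given moments."""
    if sd <= 0:
        return np.log(mean), 0.0
    var = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - var / 2.0, np.sqrt(var)


def _one_over_f(rng, n_samples, fs_hz, exponent, rms_uv, alpha_bump_gain):
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    if alpha_bump_gain > 0:
        shape *= 1.0 + alpha_bump_gain * np.exp(-0.5 * ((f - 10.0) / 1.5) ** 2)
    x = np.fft.irfft(spec * shape, n=n_samples)
    return x * (rms_uv / np.sqrt(np.mean(x**2)))


def _subject_rng(spec: CohortSpec, subject_index: int):
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(subject_index)]))


def subject_duration_multipliers(spec: CohortSpec, subject_index: int) -> np.ndarray:
    """Lognormal per-(channel, burst-class) duration multipliers for one subject.

    Drawn first from the subject's own deterministic stream so that the
    recording and the planted effect agree bit-for-bit across calls.
    """
    rng = _subject_rng(spec, subject_index)
    z = rng.standard_normal((len(spec.channel_labels), len(spec.bursts)))
    return np.exp(spec.subject_duration_sigma * z), z


def simulate_recording(spec: CohortSpec, subject_index: int):
    """Synthesize one subject's continuous recording.

    Returns ``(recording, truth)`` where ``truth`` is a DataFrame of every
    injected burst (channel, epoch, onset_s, duration_ms, freq_hz,
    amplitude, burst class index). Deterministic given
    ``(spec.seed, subject_index)``.
    """
    mult, _ = subject_duration_multipliers(spec, subject_index)
    rng = _subject_rng(spec, subject_index)
    rng.standard_normal((len(spec.channel_labels), len(spec.bursts)))  # skip multiplier draws

    n_ep = spec.n_epochs
    n_per = spec.epoch_samples
    n_total = n_ep * n_per
    fs = spec.fs_hz
    data = np.empty((len(spec.channel_labels), n_total))
    truth_rows = []
    warned = False
    for ci, ch in enumerate(spec.channel_labels):
        sig = _one_over_f(rng, n_total, fs, spec.background_exponent,
                          spec.background_rms_uv, spec.alpha_bump_gain)
        for bi, b in enumerate(spec.bursts):
            if b.rate_per_epoch <= 0:
                continue
            mu, sigma = _lognormal_params(b.duration_ms_mean * mult[ci, bi],
                                          b.duration_ms_sd * mult[ci, bi])
            counts = rng.poisson(b.rate_per_epoch, size=n_ep)
            for e in np.nonzero(counts)[0]:
                for _ in range(counts[e]):
                    dur_ms = float(rng.lognormal(mu, sigma))
                    L = int(round(dur_ms / 1000.0 * fs))
                    if L < 2:
                        L = 2
                    if L > n_per:
                        if not warned:
                            log.warning("burst (%.0f ms) longer than epoch; truncating", dur_ms)
                            warned = True
                        L = n_per
                    onset = int(rng.integers(0, n_per))
                    phase = rng.uniform(0, 2 * np.pi)
                    t = np.arange(L) / fs
                    wave = (b.amplitude_rel * spec.background_rms_uv
                            * np.hanning(L)
                            * np.cos(2 * np.pi * b.center_freq_hz * t + phase))
                    start = e * n_per + onset
                    stop = min(start + L, (e + 1) * n_per)  # clip at epoch edge
                    sig[start:stop] += wave[: stop - start]
                    truth_rows.append({
                        "channel": ch, "epoch": int(e),
                        "onset_s": onset / fs, "duration_ms": dur_ms,
                        "freq_hz": b.center_freq_hz,
                        "amplitude": b.amplitude_rel * spec.background_rms_uv,
                        "burst_class": bi,
                    })
        data[ci] = sig
    truth = pd.DataFrame(
        truth_rows,
        columns=["channel", "epoch", "onset_s", "duration_ms", "freq_hz",
                 "amplitude", "burst_class"],
    )
    return Recording(data, fs, spec.channel_labels), truth


@dataclass
class Cohort:
    """A simulated cohort: recordings, clinical table and ground truth."""

    spec: CohortSpec
    recordings: list
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame
    #: per-subject true duration means (n_subjects x n_channels x n_bursts)
    true_duration_means: np.ndarray

    @property
    def true_effect_values(self) -> np.ndarray:
        ci = self.spec.channel_labels.index(self.spec.effect_channel)
        return self.true_duration_means[:, ci, self.spec.effect_burst]


def simulate_cohort(spec: CohortSpec, arm: str = "sertraline") -> Cohort:
    """Simulate a full cohort with a planted feature-outcome coupling.

    The outcome is ``%change = intercept + effect_slope * z + noise`` with
    ``z`` the subject's standardized (population z-score) random effect on
    the effect feature's log duration mean; HAM-D post scores are then
    derived from an integer pre-treatment score. Responders are subjects
    with a decrease of at least 50%.
    """
    if arm not in ("sertraline", "placebo", "healthy_control"):
        raise ValueError(f"unknown arm {arm!r}")
    recs, truths = [], []
    z_effect = np.empty(spec.n_subjects)
    dur_means = np.empty((spec.n_subjects, len(spec.channel_labels), len(spec.bursts)))
    base = np.array([b.duration_ms_mean for b in spec.bursts])
    ci_eff = spec.channel_labels.index(spec.effect_channel)
    for i in range(spec.n_subjects):
        mult, z = subject_duration_multipliers(spec, i)
        rec, truth = simulate_recording(spec, i)
        truth.insert(0, "subject", f"S{i:03d}")
        recs.append(rec)
        truths.append(truth)
        dur_means[i] = base[None, :] * mult
        z_effect[i] = z[ci_eff, spec.effect_burst]

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2**20 + 7]))
    clinical = draw_clinical(spec, z_effect, arm, rng)
    return Cohort(spec, recs, clinical, pd.concat(truths, ignore_index=True), dur_means)


def draw_clinical(spec: CohortSpec, z_effect: np.ndarray, arm: str, rng) -> pd.DataFrame:
    """Draw the clinical table given the subjects' standardized effect values.

    Separated from :func:`simulate_cohort` so outcome-only redraws (e.g.
    null-calibration replicates at fixed EEG) follow the exact same law.
    """
    n = len(z_effect)
    pct = (spec.outcome_intercept
           + spec.effect_slope * np.asarray(z_effect, float)
           + rng.normal(0.0, spec.noise_sd, n))
    pct = np.clip(pct, -100.0, 60.0)
    lo, hi = spec.hamd_pre_range
    if arm == "healthy_control":
        hamd_pre = rng.integers(0, 8, n)
        hamd_post = hamd_pre.copy()
    else:
        hamd_pre = rng.integers(lo, hi + 1, n)
        hamd_post = np.clip(np.round(hamd_pre * (1.0 + pct / 100.0)), 0, 52).astype(int)
    age = np.clip(np.round(rng.normal(39.0, 13.0, n), 1), 18.0, 70.0)
    sex = rng.choice(["F", "M"], size=n, p=[0.7, 0.3])
    return pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "arm": arm,
        "hamd_pre": hamd_pre,
        "hamd_post": hamd_post,
        "age": age,
        "sex": sex,
    })


def match_events_to_truth(
    truth: pd.DataFrame,
    events: pd.DataFrame,
    freq_tol_hz: float = 3.0,
    time_pad_s: float = 0.1,
) -> pd.DataFrame:
    """Greedily match detected events to injected ground-truth bursts.

    A detected event matches a burst when it is in the same channel and
    epoch, its peak time falls inside the burst's (padded) time support
    and its peak frequency is within ``freq_tol_hz`` of the carrier. Each
    burst takes at most one event (the highest-power candidate). Returns
    the truth rows with matched event columns (NaN where undetected).
    """
    used = set()
    rows = []
    for _, b in truth.iterrows():
        cand = events[
            (events.channel_label == b.channel)
            & (events.epoch_index == b.epoch)
            & (events.peak_freq_hz >= b.freq_hz - freq_tol_hz)
            & (events.peak_freq_hz <= b.freq_hz + freq_tol_hz)
            & (events.peak_time_s >= b.onset_s - time_pad_s)
            & (events.peak_time_s <= b.onset_s + b.duration_ms / 1000.0 + time_pad_s)
        ]
        cand = cand[~cand.index.isin(used)]
        rec = dict(b)
        if len(cand):
            best = cand.loc[cand.peak_power_fom.idxmax()]
            used.add(best.name)
            rec.update(detected=True, det_duration_ms=best.duration_ms,
                       det_freq_hz=best.peak_freq_hz, det_power_fom=best.peak_power_fom,
                       det_span_hz=best.span_hz)
        else:
            rec.update(detected=False, det_duration_ms=np.nan, det_freq_hz=np.nan,
                       det_power_fom=np.nan, det_span_hz=np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


def percent_change(clinical: pd.DataFrame) -> pd.Series:
    """Percentage change in HAM-D, negative for improvement."""
    return 100.0 * (clinical["hamd_post"] - clinical["hamd_pre"]) / clinical["hamd_pre"]
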