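"""Spectral-event detection, FWHM measurement and SEF aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegsef.containers import DEFAULT_BANDS, NormalizedTFR, get_band
from eegsef.events import (aggregate_sef, detect_events, detect_events_multi,
                           events_to_frame, expected_blurred_duration_ms,
                           fwhm_interp, sef_columns, threshold_validation)
from eegsef.synthetic import match_events_to_truth


def brute_force_fwhm(values, peak_idx, spacing):
    """Independent oracle: locate every half-max crossing by sign change
    and linear interpolation over the whole profile, then take the
    crossings nearest the peak on each side (edges if none)."""
    half = values[peak_idx] / 2.0
    d = values - half
    xs = []
    for i in range(len(values) - 1):
        if (d[i] >= 0) != (d[i + 1] >= 0):
            xs.append(i + d[i] / (d[i] - d[i + 1]))
    left = [x for x in xs if x < peak_idx]
    right = [x for x in xs if x > peak_idx]
    lo = max(left) if left else 0.0
    hi = min(right) if right else float(len(values) - 1)
    return (hi - lo) * spacing


def _ntfr(fom, freqs=None, dt=0.02, channel="Fp1"):
    fom = np.asarray(fom, float)
    freqs = np.arange(1.0, fom.shape[0] + 1.0) if freqs is None else freqs
    times = np.arange(fom.shape[2]) * dt
    return NormalizedTFR(fom, freqs, times, channel, np.ones(fom.shape[0]))


class TestFwhm:
    def test_spec_row_oracle(self):
        row = np.array([1.0, 2.0, 8.0, 2.0, 1.0])
        width, trunc = fwhm_interp(row, 2, 10.0)
        assert not trunc
        assert width == pytest.approx(2 * (1 - 2 / 6) * 10.0, abs=1e-12)

    def test_truncated_at_edge(self):
        row = np.array([8.0, 7.0, 6.0])
        width, trunc = fwhm_interp(row, 0, 1.0)
        assert trunc and width == pytest.approx(2.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_on_smooth_profiles(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal(24)
        profile = np.convolve(np.exp(base), np.hanning(9) / 5.0, mode="same") + 0.01
        peak = int(np.argmax(profile))
        width, _ = fwhm_interp(profile, peak, 0.5)
        assert width == pytest.approx(brute_force_fwhm(profile, peak, 0.5), rel=1e-9)


class TestDetect:
    def test_uniform_fom_no_events(self):
        ntfr = _ntfr(np.ones((20, 3, 50)))
        assert detect_events(ntfr, get_band("alpha")) == []

    def test_single_bump_single_event(self):
        fom = np.ones((20, 2, 50))
        f = np.exp(-0.5 * ((np.arange(20) - 9.0) / 1.5) ** 2)
        t = np.exp(-0.5 * ((np.arange(50) - 25.0) / 4.0) ** 2)
        fom[:, 1, :] += 20.0 * np.outer(f, t)
        evs = detect_events(_ntfr(fom), get_band("alpha"))
        assert len(evs) == 1
        ev = evs[0]
        assert ev.epoch_index == 1 and ev.peak_freq_hz == 10.0
        # FWHM of the added Gaussian (sigma=4 samples, 20 ms spacing) on
        # a baseline of 1: crossing at half of peak 21
        assert ev.duration_ms == pytest.approx(
            brute_force_fwhm(fom[9, 1, :], 25, 20.0), rel=1e-9)
        assert ev.span_hz == pytest.approx(
            brute_force_fwhm(fom[:, 1, 25], 9, 1.0), rel=1e-9)

    def test_plateau_yields_single_event_at_first_scan_point(self):
        fom = np.ones((10, 1, 30))
        fom[4:6, 0, 10:12] = 9.0  # 2x2 exact plateau
        evs = detect_events_multi(_ntfr(fom), DEFAULT_BANDS[:2])
        assert len(evs) == 1
        assert evs[0].peak_freq_hz == 5.0 and evs[0].peak_time_s == pytest.approx(0.2)

    def test_two_maxima_in_one_suprathreshold_region(self):
        fom = np.ones((12, 1, 40))
        t = np.arange(40.0)
        ridge = 8.0 + 2.0 * np.cos(2 * np.pi * t / 12.0)  # twin peaks above 6
        fom[6, 0, 5:35] = ridge[5:35]
        evs = detect_events(_ntfr(fom), get_band("alpha"))
        assert len(evs) >= 2

    def test_band_outside_grid_rejected(self):
        ntfr = _ntfr(np.ones((4, 1, 10)))
        with pytest.raises(ValueError, match="band"):
            detect_events(ntfr, get_band("beta"))

    def test_threshold_monotonicity(self, small_ntfr):
        ntfr, _ = small_ntfr
        for band in DEFAULT_BANDS:
            n6 = len(detect_events(ntfr, band, 6.0))
            n4 = len(detect_events(ntfr, band, 4.0))
            n2 = len(detect_events(ntfr, band, 2.0))
            assert n6 <= n4 <= n2


class TestDetectorRecovery:
    """Validation against the generator's ground truth by event matching."""

    def test_injected_beta_bursts_are_found(self, small_features):
        """Bursts long enough to survive wavelet blur and not clipped by
        the epoch edge are almost always detected."""
        truth = small_features["truth"]
        events = events_to_frame(small_features["events"])
        bt = truth[truth.burst_class == 2]
        resolvable = bt[(bt.duration_ms >= 100.0)
                        & (bt.onset_s + bt.duration_ms / 1000.0 <= 4.8)]
        m = match_events_to_truth(resolvable, events)
        assert m.detected.mean() >= 0.9

    def test_matched_durations_near_blur_prediction(self, small_features):
        truth = small_features["truth"]
        events = events_to_frame(small_features["events"])
        m = match_events_to_truth(truth[truth.burst_class == 2], events)
        m = m[m.detected]
        predicted = np.array([
            expected_blurred_duration_ms(d, 20.0) for d in m.duration_ms
        ])
        assert abs(np.mean(m.det_duration_ms - predicted)) < 40.0

    def test_matched_duration_tracks_subject_duration_means(self):
        """Across subjects with heterogeneous beta duration means, the
        mean matched-event duration recovers the ordering (r > 0.7)."""
        import logging

        from eegsef import PipelineConfig
        from eegsef.preprocess import preprocess_recording
        from eegsef.synthetic import simulate_recording
        from eegsef.tfr import compute_tfr, normalize_fom
        from eegsef.validation import beta_only_spec
        from eegsef.events import detect_events_multi
        from eegsef.containers import DEFAULT_BANDS

        logging.disable(logging.WARNING)
        cfg = PipelineConfig()
        spec = beta_only_spec(seed=42, n_epochs=40, n_subjects=24)
        true_means, det_means = [], []
        for i in range(spec.n_subjects):
            rec, truth = simulate_recording(spec, i)
            ep = preprocess_recording(rec)
            ntfr = normalize_fom(
                compute_tfr(ep, ["Fp1"], freqs_hz=cfg.freqs(), decim=cfg.decim)["Fp1"])
            ev = events_to_frame(detect_events_multi(ntfr, DEFAULT_BANDS))
            keep = set(ep.kept_epoch_indices.tolist())
            remap = {o: n for n, o in enumerate(sorted(keep))}
            t = truth[(truth.channel == "Fp1") & truth.epoch.isin(keep)].copy()
            t["epoch"] = t["epoch"].map(remap)
            m = match_events_to_truth(t, ev)
            d = m[m.detected]
            if len(d) >= 3:
                true_means.append(t.duration_ms.mean())
                det_means.append(d.det_duration_ms.mean())
        logging.disable(logging.NOTSET)
        r = np.corrcoef(true_means, det_means)[0, 1]
        assert len(true_means) >= 20
        assert r > 0.7, f"r={r:.2f} over {len(true_means)} subjects"

    def test_recovered_peak_frequency(self, small_features):
        events = events_to_frame(small_features["events"])
        m = match_events_to_truth(
            small_features["truth"][small_features["truth"].burst_class == 2], events)
        m = m[m.detected]
        assert np.median(np.abs(m.det_freq_hz - m.freq_hz)) <= 2.0


class TestAggregate:
    def test_arithmetic_example(self):
        from eegsef.containers import SpectralEvent

        events = [
            SpectralEvent("Fp1", "beta", e, 1.0, 20.0, 10.0, d, 4.0)
            for e, d in enumerate([100.0, 150.0, 200.0])
        ]
        sef = aggregate_sef(events, 71, ("Fp1",))
        assert sef["Fp1_beta_rate"] == pytest.approx(3 / 71)
        assert sef["Fp1_beta_duration"] == pytest.approx(150.0)
        assert np.isnan(sef["Fp1_alpha_duration"])
        assert sef["Fp1_alpha_rate"] == 0.0

    def test_empty_events_all_rates_zero_rest_missing(self):
        channels = ("Fp1", "Fp2")
        sef = aggregate_sef([], 10, channels)
        rates = sef[[c for c in sef.index if c.endswith("_rate")]]
        others = sef[[c for c in sef.index if not c.endswith("_rate")]]
        assert (rates == 0).all() and others.isna().all()

    def test_full_vector_is_84_entries(self):
        channels = tuple(f"c{i}" for i in range(7))
        assert len(sef_columns(channels)) == 84
        assert len(aggregate_sef([], 5, channels)) == 84

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_sef([], 0, ("Fp1",))


class TestThresholdValidation:
    def test_burst_dominated_high_correlation(self, small_ntfr):
        ntfr, _ = small_ntfr
        table = threshold_validation({"Fp1": ntfr})
        beta = table[table.band == "beta"].set_index("cutoff")["r"]
        assert (beta > 0.5).all()

    def test_constant_fom_undefined(self):
        ntfr = _ntfr(np.ones((20, 4, 30)))
        table = threshold_validation({"Fp1": ntfr})
        assert table["r"].isna().all()

    def test_needs_three_epochs(self):
        ntfr = _ntfr(np.ones((20, 2, 30)))
        with pytest.raises(ValueError):
            threshold_validation({"Fp1": ntfr})
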