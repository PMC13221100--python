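"""Transient spectral-event detection and per-subject feature aggregation.

An *event* is a strict 2-D local maximum of the factor-of-median TFR
within an epoch whose value reaches the detection threshold (default 6x
the per-frequency median) and whose peak frequency lies inside a band.
Multiple qualifying maxima inside one connected suprathreshold region
each count as separate events. Event extent is measured as full width at
half maximum: the half-max level is half the peak FOM value, crossings
are located by linear interpolation along the peak's frequency row (time
axis -> duration) and time column (frequency axis -> span), and the
search stops at the epoch/grid edges, flagging the event ``truncated``
when an edge is hit before the level is crossed.

Per-subject Spectral Event Features (SEF) are the event rate per epoch
and the means of event FOM power, duration and frequency span, per
channel and band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import DEFAULT_BANDS, Band, NormalizedTFR, SpectralEvent

SEF_FEATURES = ("power", "rate", "duration", "span")

_NEIGHBORS = np.ones((3, 3), dtype=bool)
_NEIGHBORS[1, 1] = False


def fwhm_interp(values: np.ndarray, peak_idx: int, spacing: float):
    """Full width at half maximum around ``values[peak_idx]``.

    Walks outward from the peak until the profile drops below half the
    peak value, locating each crossing by linear interpolation between
    the straddling samples. If an edge is reached first, the width on
    that side is measured to the edge and the result flagged truncated.

    Returns ``(width, truncated)`` in units of ``spacing``.
    """
    peak = values[peak_idx]
    half = peak / 2.0
    n = len(values)

    # left side
    i = peak_idx
    while i > 0 and values[i - 1] >= half:
        i -= 1
    if i == 0 and values[0] >= half:
        left, trunc_l = float(peak_idx), True
    else:
        frac = (values[i] - half) / (values[i] - values[i - 1])
        left, trunc_l = peak_idx - i + frac, False

    # right side
    j = peak_idx
    while j < n - 1 and values[j + 1] >= half:
        j += 1
    if j == n - 1 and values[n - 1] >= half:
        right, trunc_r = float(n - 1 - peak_idx), True
    else:
        frac = (values[j] - half) / (values[j] - values[j + 1])
        right, trunc_r = j - peak_idx + frac, False

    return (left + right) * spacing, (trunc_l or trunc_r)


def _local_maxima(plane: np.ndarray, threshold: float) -> np.ndarray:
    """Strict 8-connected local maxima of a 2-D plane at/above threshold.

    A plateau (exact ties) that dominates its surroundings contributes a
    single detection at its first point in row-major scan order.
    """
    neigh_max = ndimage.maximum_filter(plane, footprint=_NEIGHBORS, mode="constant", cval=-np.inf)
    strict = (plane > neigh_max) & (plane >= threshold)
    ties = (plane == neigh_max) & (plane >= threshold)
    if ties.any():
        # keep the first scan-order point of any plateau not adjacent to a
        # strictly larger value
        labels, nlab = ndimage.label(ties, structure=np.ones((3, 3), bool))
        for lab in range(1, nlab + 1):
            mask = labels == lab
            if np.max(neigh_max[mask]) <= np.max(plane[mask]):
                idx = np.argwhere(mask)
                strict[tuple(idx[0])] = True
    return np.argwhere(strict)


# footprint for per-epoch 2-D neighbourhoods on a (freq, epoch, time) stack
_NEIGHBORS_3D = np.ones((3, 1, 3), dtype=bool)
_NEIGHBORS_3D[1, 0, 1] = False


def _find_peaks_stack(fom: np.ndarray, threshold: float) -> np.ndarray:
    """Suprathreshold strict local maxima over a (freq, epoch, time) stack.

    Epochs are independent planes (the epoch axis is not a neighbourhood
    direction). Vectorised over epochs; the coarse pass runs in float32
    for speed, and any epoch showing plateau ties at that precision is
    redone with the exact 2-D scan-order rule in full precision.
    """
    f32 = np.asarray(fom, dtype=np.float32)
    neigh_max = ndimage.maximum_filter(f32, footprint=_NEIGHBORS_3D,
                                       mode="constant", cval=-np.inf)
    supra = f32 >= threshold
    strict = (f32 > neigh_max) & supra
    tie_epochs = np.unique(np.nonzero((f32 == neigh_max) & supra)[1])
    peaks = np.argwhere(strict)
    if tie_epochs.size:
        keep = ~np.isin(peaks[:, 1], tie_epochs)
        redone = [
            np.column_stack([idx[:, 0], np.full(len(idx), e, int), idx[:, 1]])
            for e in tie_epochs
            if len(idx := _local_maxima(fom[:, e, :], threshold))
        ]
        peaks = np.vstack([peaks[keep]] + redone) if redone else peaks[keep]
    return peaks


def detect_events_multi(
    ntfr: NormalizedTFR,
    bands=DEFAULT_BANDS,
    threshold_fom: float = 6.0,
) -> list:
    """Detect suprathreshold transient events in several bands at once.

    Maxima are found on the full frequency grid (a band only filters by
    *peak* frequency; events are never split at band edges) in a single
    vectorised pass, then assigned to the band containing their peak.
    """
    for band in bands:
        if not band.mask(ntfr.freqs_hz).any():
            raise ValueError(f"band {band.name} has no frequencies on the grid")
    dt = float(ntfr.times_s[1] - ntfr.times_s[0]) if len(ntfr.times_s) > 1 else 1.0
    df = float(ntfr.freqs_hz[1] - ntfr.freqs_hz[0]) if len(ntfr.freqs_hz) > 1 else 1.0

    events = []
    for fi, e, ti in _find_peaks_stack(ntfr.fom, threshold_fom):
        f0 = ntfr.freqs_hz[fi]
        band = next((b for b in bands if b.low_hz <= f0 <= b.high_hz), None)
        if band is None:
            continue
        plane = ntfr.fom[:, e, :]
        dur, tr_t = fwhm_interp(plane[fi, :], ti, dt)
        span, tr_f = fwhm_interp(plane[:, ti], fi, df)
        events.append(
            SpectralEvent(
                channel_label=ntfr.channel_label,
                band_name=band.name,
                epoch_index=int(e),
                peak_time_s=float(ntfr.times_s[ti]),
                peak_freq_hz=float(f0),
                peak_power_fom=float(plane[fi, ti]),
                duration_ms=float(dur * 1000.0),
                span_hz=float(span),
                truncated=bool(tr_t or tr_f),
            )
        )
    events.sort(key=lambda ev: (ev.epoch_index, ev.peak_time_s, ev.peak_freq_hz))
    return events


def detect_events(
    ntfr: NormalizedTFR,
    band: Band,
    threshold_fom: float = 6.0,
) -> list:
    """Detect suprathreshold transient events of one ``band``."""
    return detect_events_multi(ntfr, [band], threshold_fom)


def expected_blurred_duration_ms(
    duration_ms: float, freq_hz: float, n_cycles: float = 7.0
) -> float:
    """Predicted detected duration of a Hann burst after wavelet smoothing.

    The TFR amplitude envelope of a narrowband Hann burst is its Hann
    envelope convolved with the wavelet's Gaussian temporal kernel
    (sigma_t = n_cycles / (2 pi f)); the detector measures FWHM on the
    *squared* envelope. Evaluated numerically on a 1-ms grid.
    """
    from .tfr import wavelet_sigma_t

    dt = 1.0  # ms
    sig_ms = wavelet_sigma_t(freq_hz, n_cycles) * 1000.0
    L = max(int(round(duration_ms)), 2)
    pad = int(np.ceil(5 * sig_ms))
    env = np.zeros(L + 2 * pad)
    env[pad : pad + L] = np.hanning(L)
    k = np.arange(-pad, pad + 1, dtype=float)
    kern = np.exp(-0.5 * (k / sig_ms) ** 2)
    blurred = np.convolve(env, kern / kern.sum(), mode="same") ** 2
    peak = int(np.argmax(blurred))
    width, _ = fwhm_interp(blurred, peak, dt)
    return float(width)


def events_to_frame(events) -> pd.DataFrame:
    cols = [
        "channel_label", "band_name", "epoch_index", "peak_time_s",
        "peak_freq_hz", "peak_power_fom", "duration_ms", "span_hz", "truncated",
    ]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(ev) for ev in events])[cols]


def aggregate_sef(
    events,
    n_epochs: int,
    channels,
    bands=DEFAULT_BANDS,
    subject_id=None,
) -> pd.Series:
    """Per-subject SEF vector from that subject's detected events.

    Rate is event count divided by the number of kept epochs (events per
    5-s epoch); power/duration/span are arithmetic means over events and
    are missing (NaN) for channel-band cells without any event.
    Columns follow the layout ``<channel>_<band>_<feature>``.
    """
    if n_epochs <= 0:
        raise ValueError("n_epochs must be positive")
    df = events_to_frame(events)
    src = {"power": "peak_power_fom", "duration": "duration_ms", "span": "span_hz"}
    values = {}
    for ch in channels:
        for band in bands:
            sel = df[(df.channel_label == ch) & (df.band_name == band.name)] if len(df) else df
            n = len(sel)
            for feat in SEF_FEATURES:
                key = f"{ch}_{band.name}_{feat}"
                if feat == "rate":
                    values[key] = n / n_epochs
                else:
                    values[key] = float(sel[src[feat]].mean()) if n else np.nan
    s = pd.Series(values)
    s.name = subject_id
    return s


def sef_columns(channels, bands=DEFAULT_BANDS):
    """Canonical SEF column order: channel-major, then band, then feature."""
    cols = []
    for ch in channels:
        for band in bands:
            for feat in SEF_FEATURES:
                cols.append(f"{ch}_{band.name}_{feat}")
    return cols


def threshold_validation(
    ntfr_by_channel: dict,
    bands=DEFAULT_BANDS,
    cutoffs=(2.0, 4.0, 6.0),
    unit: str = "epoch",
) -> pd.DataFrame:
    """Correlate suprathreshold "event area" power with mean band power.

    For each band and cutoff, per epoch: (a) the summed FOM power over
    suprathreshold (>= cutoff) band points and (b) the mean FOM band
    power over all points; channels pooled by summation. ``r`` is the
    Pearson correlation of (a) against (b) across epochs (``unit='epoch'``,
    the default). With ``unit='subject'``, pass a *list* of per-subject
    channel dicts: (a) and (b) are totalled per subject and correlated
    across subjects. A degenerate series (zero variance) records NaN
    rather than 0.
    """
    if unit == "subject":
        if not isinstance(ntfr_by_channel, (list, tuple)):
            raise ValueError("unit='subject' expects a list of per-subject dicts")
        if len(ntfr_by_channel) < 3:
            raise ValueError("threshold_validation needs >= 3 subjects")
        per_subj = [threshold_validation(d, bands, cutoffs, unit="_totals")
                    for d in ntfr_by_channel]
        rows = []
        for band in bands:
            for cut in cutoffs:
                a = np.array([t[(band.name, cut)][0] for t in per_subj])
                b = np.array([t[(band.name, cut)][1] for t in per_subj])
                r = np.nan if (np.std(a) == 0 or np.std(b) == 0) \
                    else float(np.corrcoef(a, b)[0, 1])
                rows.append({"band": band.name, "cutoff": cut, "r": r})
        return pd.DataFrame(rows)
    if unit not in ("epoch", "_totals"):
        raise ValueError("unit must be 'epoch' or 'subject'")
    rows = []
    totals = {}
    for band in bands:
        per_epoch_area = None
        per_epoch_mean = None
        for ntfr in ntfr_by_channel.values():
            fmask = band.mask(ntfr.freqs_hz)
            sub = ntfr.fom[fmask]  # (f, e, t)
            mean_e = sub.mean(axis=(0, 2))
            if per_epoch_mean is None:
                n_e = sub.shape[1]
                per_epoch_mean = np.zeros(n_e)
                per_epoch_area = {c: np.zeros(n_e) for c in cutoffs}
            per_epoch_mean += mean_e
            for cut in cutoffs:
                per_epoch_area[cut] += np.where(sub >= cut, sub, 0.0).sum(axis=(0, 2))
        if unit == "_totals":
            for cut in cutoffs:
                totals[(band.name, cut)] = (float(per_epoch_area[cut].sum()),
                                            float(per_epoch_mean.sum()))
            continue
        if per_epoch_mean is None or len(per_epoch_mean) < 3:
            raise ValueError("threshold_validation needs >= 3 epochs")
        for cut in cutoffs:
            a, b = per_epoch_area[cut], per_epoch_mean
            if np.std(a) == 0 or np.std(b) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            rows.append({"band": band.name, "cutoff": cut, "r": r})
    if unit == "_totals":
        return totals
    return pd.DataFrame(rows)
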