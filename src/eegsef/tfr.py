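"""Morlet wavelet time-frequency decomposition and factor-of-median
normalisation.

The transform convolves each 5-s epoch with complex Morlet wavelets
(fixed number of cycles at every frequency, default 7, on a 1-Hz grid
from 1 to 30 Hz) and returns squared magnitude. Wavelets are applied in
the frequency domain: each wavelet's spectrum is a Gaussian centred on
its carrier with sigma_f = f / n_cycles, which is sampled directly on
the padded DFT grid. Amplitudes are scaled so that the power of a
stationary unit-RMS sinusoid at a grid frequency reads ~1.

Because the wavelet spectrum occupies a narrow band, the product
spectrum can be folded modulo N/decim before the inverse FFT, which
yields the time-decimated convolution at a fraction of the cost — the
identity ``ifft(fold(Y, d))[m] = ifft(Y)[m*d] / d`` holds for any
spectrum, so the output is a plain subsampling of the full-rate
transform (exact in exact arithmetic; float32 rounding only).

At the lowest frequencies a 7-cycle wavelet outlasts a 5-s epoch; those
rows are still computed (the convolution sees the zero-padded epoch) but
are flagged with a log warning, matching the convention of reporting the
full 1-30 Hz grid while trusting only frequencies whose wavelet fits.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.fft as sfft

from .containers import EpochedEEG, NormalizedTFR, TFR

log = logging.getLogger(__name__)

#: Default analysis grid: 1..30 Hz inclusive, 1-Hz steps.
DEFAULT_FREQS = np.arange(1.0, 31.0)


def wavelet_sigma_t(freq_hz: float, n_cycles: float = 7.0) -> float:
    """Temporal standard deviation (s) of the Morlet envelope at ``freq_hz``."""
    return n_cycles / (2.0 * np.pi * freq_hz)


def _fft_length(n_samples: int, decim: int) -> int:
    """Padded FFT length: fast, >= 2*n, and a multiple of ``decim``."""
    n = sfft.next_fast_len(2 * n_samples)
    while n % decim:
        n = sfft.next_fast_len(n + 1)
    return n


def _wavelet_spectra(freqs_hz, n_cycles, n_fft, fs_hz):
    """Sampled analytic-Morlet spectra on the DFT grid, one row per frequency.

    Returns (support index array, spectrum values) pairs; bins below 1e-6
    of the Gaussian peak are dropped.
    """
    fgrid = np.fft.fftfreq(n_fft, d=1.0 / fs_hz)
    out = []
    for f0 in freqs_hz:
        sigma_f = f0 / n_cycles
        w = np.exp(-0.5 * ((fgrid - f0) / sigma_f) ** 2)
        w[fgrid <= 0] = 0.0  # analytic: positive frequencies only
        idx = np.nonzero(w > 1e-6)[0]
        out.append((idx, (np.sqrt(2.0) * w[idx]).astype(np.complex64)))
    return out


def compute_tfr(
    ep: EpochedEEG,
    channels=None,
    freqs_hz=None,
    n_cycles: float = 7.0,
    decim: int = 1,
) -> dict:
    """Morlet TFR for one or more channels of an epoched recording.

    Parameters
    ----------
    ep : EpochedEEG
    channels : sequence of str, optional
        Channel labels (default: all).
    freqs_hz : array-like, optional
        Strictly increasing frequency grid (default 1..30 Hz, 1-Hz step).
    n_cycles : float
        Morlet cycles at every frequency.
    decim : int
        Integer time-decimation factor of the output grid.

    Returns
    -------
    dict mapping channel label -> :class:`TFR` with power of shape
    (n_freqs, n_epochs, ceil(n_samples/decim)).
    """
    if channels is None:
        channels = ep.channel_labels
    freqs_hz = DEFAULT_FREQS.copy() if freqs_hz is None else np.asarray(freqs_hz, float)
    if np.any(np.diff(freqs_hz) <= 0):
        raise ValueError("freqs_hz must be strictly increasing")
    if freqs_hz[-1] >= ep.fs_hz / 2:
        raise ValueError("requested frequency at or above Nyquist")
    decim = int(decim)
    if decim < 1:
        raise ValueError("decim must be >= 1")

    n = ep.n_samples
    slow = [f for f in freqs_hz if 2 * 3.5 * wavelet_sigma_t(f, n_cycles) > ep.epoch_s]
    if slow:
        log.warning(
            "wavelet support exceeds the %.3gs epoch at %s Hz; "
            "edge effects dominate these rows",
            ep.epoch_s,
            slow,
        )

    n_fft = _fft_length(n, decim)
    n_fold = n_fft // decim
    n_t = -(-n // decim)  # ceil
    times = np.arange(n_t) * (decim / ep.fs_hz)
    spectra = _wavelet_spectra(freqs_hz, n_cycles, n_fft, ep.fs_hz)

    ch_idx = [ep.channel_index(c) for c in channels]
    rows = ep.data[ch_idx].reshape(len(ch_idx) * ep.n_epochs, n).astype(np.float32)
    xp = np.zeros((rows.shape[0], n_fft), dtype=np.float32)
    xp[:, :n] = rows
    # analytic wavelets live on positive frequencies only, so the real
    # FFT's half-spectrum is all that is ever multiplied
    X = sfft.rfft(xp, axis=1)
    del xp

    power = np.empty((len(freqs_hz), rows.shape[0], n_t), dtype=np.float32)
    Yf = np.empty((rows.shape[0], n_fold), dtype=np.complex64)
    for i, (idx, w) in enumerate(spectra):
        Yf[:] = 0.0
        band = X[:, idx] * w
        # fold the product spectrum modulo n_fold -> exact decimation
        tgt = idx % n_fold
        seg = idx // n_fold
        for k in np.unique(seg):
            m = seg == k
            Yf[:, tgt[m]] += band[:, m]
        y = sfft.ifft(Yf, axis=1)
        np.abs(y[:, :n_t], out=power[i].view(np.float32))
        np.square(power[i], out=power[i])
    # ifft(fold(Y, d)) = d * ifft(Y)[::d]: undo the fold's amplitude factor
    if decim > 1:
        power /= float(decim) ** 2

    out = {}
    for j, label in enumerate(channels):
        p = power[:, j * ep.n_epochs : (j + 1) * ep.n_epochs, :].astype(np.float64)
        out[label] = TFR(p, freqs_hz.copy(), times.copy(), label)
    return out


def morlet_tfr(
    ep: EpochedEEG,
    channel: str,
    freqs_hz=None,
    n_cycles: float = 7.0,
    decim: int = 1,
) -> TFR:
    """Single-channel convenience wrapper around :func:`compute_tfr`."""
    return compute_tfr(ep, [channel], freqs_hz, n_cycles, decim)[channel]


def normalize_fom(tfr: TFR) -> NormalizedTFR:
    """Factor-of-median normalisation.

    Every frequency row is divided by the median of its power pooled over
    *all* epochs and time points, so the normalised units relate each
    point to the typical resting-state power of the whole recording at
    that frequency.
    """
    med = np.median(tfr.power, axis=(1, 2))
    if np.any(med <= 0):
        bad = tfr.freqs_hz[med <= 0]
        raise ValueError(f"zero median power at {bad} Hz — degenerate signal")
    fom = tfr.power / med[:, None, None]
    return NormalizedTFR(fom, tfr.freqs_hz, tfr.times_s, tfr.channel_label, med)
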