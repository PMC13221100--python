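"""Core data containers shared across the pipeline.

The pipeline operates on a small set of immutable-ish containers:
continuous multichannel EEG (:class:`Recording`), fixed-length cleaned
segments (:class:`EpochedEEG`), per-channel Morlet time-frequency power
(:class:`TFR` and its factor-of-median normalised form
:class:`NormalizedTFR`), frequency bands (:class:`Band`) and detected
transient spectral events (:class:`SpectralEvent`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard 10-20 frontal montage used throughout.
FRONTAL_CHANNELS = ("Fp1", "Fp2", "Fz", "F4", "F3", "F7", "F8")


@dataclass
class Band:
    """A frequency band, inclusive of both edges on the 1-Hz analysis grid."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low_hz must be < high_hz")

    def mask(self, freqs_hz: np.ndarray) -> np.ndarray:
        return (freqs_hz >= self.low_hz) & (freqs_hz <= self.high_hz)


#: Default band layout: a low-frequency delta/theta band, an alpha band
#: centred on the closed-eyes alpha peak, and a broad beta band.
DEFAULT_BANDS = (
    Band("delta_theta", 2.0, 5.0),
    Band("alpha", 6.0, 14.0),
    Band("beta", 15.0, 29.0),
)


def get_band(name: str, bands=DEFAULT_BANDS) -> Band:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs_hz : float
        Sampling rate. Must leave headroom above the 50 Hz low-pass edge.
    channel_labels : tuple of str
        10-20 channel names, one per row of ``data``.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: tuple

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if not np.isfinite(self.data).all():
            raise ValueError("Recording contains non-finite samples")
        if self.fs_hz <= 100:
            raise ValueError("fs_hz must exceed 100 Hz (Nyquist above filter edge)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class EpochedEEG:
    """Cleaned EEG tiled into fixed-length epochs.

    ``data`` has shape (n_channels, n_epochs, n_samples_per_epoch); epochs
    are the non-overlapping survivors of artifact rejection and
    ``kept_epoch_indices`` maps them back to their position in the
    continuous recording.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: tuple
    kept_epoch_indices: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        self.kept_epoch_indices = np.asarray(self.kept_epoch_indices, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("EpochedEEG.data must be 3-D (ch x epoch x sample)")
        if np.any(np.diff(self.kept_epoch_indices) <= 0):
            raise ValueError("kept_epoch_indices must be strictly increasing")
        if len(self.kept_epoch_indices) != self.data.shape[1]:
            raise ValueError("kept_epoch_indices length must match epoch count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class TFR:
    """Single-channel Morlet time-frequency power, one plane per epoch.

    ``power`` has shape (n_freqs, n_epochs, n_times) in squared-amplitude
    units; ``times_s`` is the within-epoch time grid (possibly decimated
    relative to the raw sampling rate).
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    channel_label: str

    def __post_init__(self) -> None:
        if self.power.ndim != 3:
            raise ValueError("TFR.power must be 3-D (freq x epoch x time)")
        if np.any(self.power < 0):
            raise ValueError("TFR power must be non-negative")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")


@dataclass
class NormalizedTFR:
    """Factor-of-median (FOM) normalised TFR.

    Each frequency row is divided by its median power pooled over all
    epochs and time points of the recording, so a value of 6 means "six
    times the typical power at that frequency".
    """

    fom: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    channel_label: str
    median_per_freq: np.ndarray = field(default=None)


@dataclass
class SpectralEvent:
    """One detected transient spectral event (suprathreshold TFR peak)."""

    channel_label: str
    band_name: str
    epoch_index: int
    peak_time_s: float
    peak_freq_hz: float
    peak_power_fom: float
    duration_ms: float
    span_hz: float
    truncated: bool = False
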