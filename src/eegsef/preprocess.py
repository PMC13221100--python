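"""Resting-state EEG cleaning: band-pass filter, common-average reference,
amplitude/kurtosis epoch rejection and tiling into fixed-length epochs.

The canonical order is ``bandpass -> common_average_reference ->
reject_and_epoch`` (see :func:`preprocess_recording`). Filtering is
zero-phase (forward-backward 4th-order Butterworth) so that burst timing —
and hence downstream event durations — is not shifted.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal
from scipy.stats import kurtosis

from .containers import EpochedEEG, Recording

log = logging.getLogger(__name__)


def bandpass(rec: Recording, low_hz: float = 0.5, high_hz: float = 50.0) -> Recording:
    """Zero-phase band-pass filter between ``low_hz`` and ``high_hz``.

    Applies a 4th-order Butterworth filter forward and backward
    (``sosfiltfilt``), removing DC and line-adjacent content while leaving
    passband amplitudes essentially untouched.
    """
    nyq = rec.fs_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=rec.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(filtered, rec.fs_hz, rec.channel_labels)


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average: subtract the across-channel mean
    at every sample. Idempotent."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data, rec.fs_hz, rec.channel_labels)


def reject_and_epoch(
    rec: Recording,
    epoch_s: float = 5.0,
    amp_uv: float = 150.0,
    kurt_z: float = 5.0,
) -> EpochedEEG:
    """Tile into non-overlapping ``epoch_s``-second epochs and drop noisy ones.

    An epoch is rejected when its peak absolute amplitude exceeds
    ``amp_uv`` on any channel, or when any channel's sample kurtosis is a
    ``kurt_z``-sigma outlier relative to that channel's distribution of
    epoch kurtoses. Remainder samples at the end of the recording are
    discarded. ``amp_uv`` / ``kurt_z`` may be ``inf`` to disable a rule.
    """
    n_per = int(round(epoch_s * rec.fs_hz))
    if abs(epoch_s * rec.fs_hz - n_per) > 1e-9:
        raise ValueError("epoch_s x fs_hz must be an integer sample count")
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    tiled = rec.data[:, : n_epochs * n_per].reshape(rec.n_channels, n_epochs, n_per)

    peak = np.abs(tiled).max(axis=(0, 2))  # per epoch
    amp_ok = peak <= amp_uv

    # kurtosis z-scored across epochs, per channel
    k = kurtosis(tiled, axis=2, fisher=True, bias=True)  # (ch, epoch)
    mu = k.mean(axis=1, keepdims=True)
    sd = k.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        kz = np.where(sd > 0, (k - mu) / sd, 0.0)
    kurt_ok = (np.abs(kz) <= kurt_z).all(axis=0)

    keep = amp_ok & kurt_ok
    kept = np.nonzero(keep)[0]
    if kept.size == 0:
        raise ValueError(
            "all epochs rejected — review amp_uv/kurt_z thresholds against the data"
        )
    n_drop = n_epochs - kept.size
    if n_drop:
        log.info("rejected %d/%d epochs (amplitude or kurtosis)", n_drop, n_epochs)
    return EpochedEEG(tiled[:, kept, :], rec.fs_hz, rec.channel_labels, kept)


def preprocess_recording(
    rec: Recording,
    low_hz: float = 0.5,
    high_hz: float = 50.0,
    epoch_s: float = 5.0,
    amp_uv: float = 150.0,
    kurt_z: float = 5.0,
) -> EpochedEEG:
    """Full cleaning chain: filter, common-average reference, reject+epoch."""
    rec = bandpass(rec, low_hz, high_hz)
    rec = common_average_reference(rec)
    return reject_and_epoch(rec, epoch_s=epoch_s, amp_uv=amp_uv, kurt_z=kurt_z)
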