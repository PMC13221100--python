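"""Averaged Power Features (APF): absolute and relative band power,
cordance, and orthogonalized power-envelope connectivity (PEC).

Band powers are taken from the same Morlet TFR used for event detection
(one spectral estimator for the whole pipeline). Cordance follows the
"mean of z-scored absolute and z-scored relative power" definition, with
the z-score population being the channels of one subject within a band
(an across-subject variant is available). PEC uses pairwise time-domain
orthogonalization of analytic signals: for an ordered pair (x, y) the
component of y's analytic signal instantaneously collinear with x's is
removed, and the amplitude envelopes of x and of the residual are
correlated over (by default) concatenated epochs; the two directed
values are averaged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import DEFAULT_BANDS, Band, EpochedEEG

log = logging.getLogger(__name__)


def band_powers(tfr_by_channel: dict, bands=DEFAULT_BANDS):
    """Absolute and relative band power per channel.

    Absolute band power integrates the time-averaged TFR over the band's
    frequency bins (sum over the 1-Hz grid of the power averaged across
    epochs and times); "overall" integrates the full analysis grid, so
    band powers partition it and relative power (band / overall) lies in
    (0, 1], summing over the three bands to <= 1 because the bands do not
    tile the grid.

    Returns ``(absolute, relative)``: DataFrames indexed by channel with
    band-name columns (absolute additionally has an ``overall`` column).
    """
    abs_rows, rel_rows = {}, {}
    for ch, tfr in tfr_by_channel.items():
        per_freq = tfr.power.mean(axis=(1, 2))  # time/epoch-averaged spectrum
        overall = float(per_freq.sum())
        if overall <= 0:
            raise ValueError(f"channel {ch}: zero all-band power")
        row = {"overall": overall}
        for band in bands:
            row[band.name] = float(per_freq[band.mask(tfr.freqs_hz)].sum())
        abs_rows[ch] = row
        rel_rows[ch] = {b.name: row[b.name] / overall for b in bands}
    absolute = pd.DataFrame.from_dict(abs_rows, orient="index")
    relative = pd.DataFrame.from_dict(rel_rows, orient="index")
    return absolute, relative


def cordance(absolute: pd.DataFrame, relative: pd.DataFrame, bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Cordance per channel and band: mean of z-scored absolute and
    z-scored relative power, z-scored across this subject's channels."""
    if len(absolute) < 3:
        raise ValueError("cordance needs >= 3 channels to z-score across")
    out = {}
    for band in bands:
        a = absolute[band.name].to_numpy(float)
        r = relative[band.name].to_numpy(float)
        for name, v in (("absolute", a), ("relative", r)):
            if np.std(v) == 0:
                raise ValueError(
                    f"cordance: zero variance of {name} power across channels in "
                    f"band {band.name} (identical channels?)"
                )
        za = (a - a.mean()) / a.std()
        zr = (r - r.mean()) / r.std()
        out[band.name] = (za + zr) / 2.0
    return pd.DataFrame(out, index=absolute.index)


def cordance_across_subjects(absolute_by_subject: dict, relative_by_subject: dict,
                             bands=DEFAULT_BANDS) -> dict:
    """Cordance variant with the z-score population taken across subjects
    (per channel and band) instead of across channels within subject.

    ``absolute_by_subject``/``relative_by_subject`` map subject id to the
    tables of :func:`band_powers`. Returns a dict subject id -> DataFrame
    (channels x bands).
    """
    subjects = list(absolute_by_subject)
    if len(subjects) < 3:
        raise ValueError("across-subject cordance needs >= 3 subjects")
    out = {s: {} for s in subjects}
    channels = absolute_by_subject[subjects[0]].index
    for band in bands:
        a = np.array([[absolute_by_subject[s].loc[ch, band.name] for ch in channels]
                      for s in subjects])
        r = np.array([[relative_by_subject[s].loc[ch, band.name] for ch in channels]
                      for s in subjects])
        for name, v in (("absolute", a), ("relative", r)):
            if np.any(v.std(axis=0) == 0):
                raise ValueError(f"zero {name}-power variance across subjects "
                                 f"in band {band.name}")
        za = (a - a.mean(axis=0)) / a.std(axis=0)
        zr = (r - r.mean(axis=0)) / r.std(axis=0)
        cord = (za + zr) / 2.0
        for si, s in enumerate(subjects):
            out[s][band.name] = cord[si]
    return {s: pd.DataFrame(v, index=channels) for s, v in out.items()}


def _orthogonalized_envelopes(ax: np.ndarray, ay: np.ndarray):
    """Envelope of y after removing its component collinear with x, per
    time point (analytic signals in, envelopes out)."""
    denom = np.abs(ax)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = np.abs(np.imag(ay * np.conj(ax) / denom))
    return resid


def pec(
    ep: EpochedEEG,
    band: Band,
    concatenate_epochs: bool = True,
    filter_order: int = 4,
) -> pd.DataFrame:
    """Power-envelope connectivity matrix for one band.

    Channels are band-pass filtered (zero-phase Butterworth), the
    analytic signal is taken per epoch, each ordered pair is
    orthogonalized, and amplitude envelopes are Pearson-correlated
    (over concatenated epochs by default, else per epoch then averaged).
    The matrix is symmetric by construction: PEC(x,y) is the mean of the
    two directed correlations. A zero-variance residual envelope (e.g.
    identical channels) records 0 with a warning.
    """
    if ep.n_channels < 2:
        raise ValueError("PEC needs >= 2 channels")
    sos = sps.butter(filter_order, [band.low_hz, band.high_hz], btype="bandpass",
                     fs=ep.fs_hz, output="sos")
    filt = sps.sosfiltfilt(sos, ep.data, axis=2)
    analytic = sps.hilbert(filt, axis=2)  # (ch, epoch, time)

    n = ep.n_channels
    labels = list(ep.channel_labels)
    mat = np.eye(n)

    def _corr(u, v):
        # a residual envelope at rounding-noise level (e.g. identical
        # channels) is degenerate, not a real signal to correlate
        if np.std(u) == 0 or np.std(v) == 0 or np.mean(v) < 1e-8 * np.mean(u):
            return None
        return float(np.corrcoef(u, v)[0, 1])

    for i in range(n):
        for j in range(i + 1, n):
            vals = []
            for (a, b) in ((i, j), (j, i)):
                env_a = np.abs(analytic[a])
                env_res = _orthogonalized_envelopes(analytic[a], analytic[b])
                if concatenate_epochs:
                    c = _corr(env_a.ravel(), env_res.ravel())
                    cs = [c] if c is not None else []
                else:
                    cs = [c for e in range(ep.n_epochs)
                          if (c := _corr(env_a[e], env_res[e])) is not None]
                if not cs:
                    log.warning("PEC %s->%s: zero-variance residual envelope; "
                                "recording 0", labels[a], labels[b])
                    cs = [0.0]
                vals.append(np.mean(cs))
            mat[i, j] = mat[j, i] = float(np.mean(vals))
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=labels, columns=labels)


def channel_pairs(channels):
    """Ordered unique channel pairs, row-major upper triangle."""
    return [(a, b) for k, a in enumerate(channels) for b in channels[k + 1:]]


def aggregate_apf(
    tfr_by_channel: dict,
    ep: EpochedEEG,
    bands=DEFAULT_BANDS,
    subject_id=None,
    concatenate_epochs: bool = True,
) -> pd.Series:
    """Flat per-subject APF vector.

    Layout (7 channels, 3 bands -> 133 values): absolute power per channel
    x (overall + bands) = 28, relative per channel x band = 21, cordance
    per channel x band = 21, PEC per channel pair x band = 63. Columns are
    ``<channel>_<band>_<feature>`` and ``<chA>-<chB>_<band>_pec``.
    """
    absolute, relative = band_powers(tfr_by_channel, bands)
    cord = cordance(absolute, relative, bands)
    channels = list(tfr_by_channel.keys())
    values = {}
    for ch in channels:
        values[f"{ch}_overall_absolute"] = absolute.loc[ch, "overall"]
        for band in bands:
            values[f"{ch}_{band.name}_absolute"] = absolute.loc[ch, band.name]
    for ch in channels:
        for band in bands:
            values[f"{ch}_{band.name}_relative"] = relative.loc[ch, band.name]
    for ch in channels:
        for band in bands:
            values[f"{ch}_{band.name}_cordance"] = cord.loc[ch, band.name]
    for band in bands:
        m = pec(ep, band, concatenate_epochs=concatenate_epochs)
        for a, b in channel_pairs(channels):
            values[f"{a}-{b}_{band.name}_pec"] = m.loc[a, b]
    s = pd.Series(values)
    s.name = subject_id
    return s


def apf_columns(channels, bands=DEFAULT_BANDS):
    """Canonical APF column order (see :func:`aggregate_apf`)."""
    cols = []
    for ch in channels:
        cols.append(f"{ch}_overall_absolute")
        cols += [f"{ch}_{b.name}_absolute" for b in bands]
    for ch in channels:
        cols += [f"{ch}_{b.name}_relative" for b in bands]
    for ch in channels:
        cols += [f"{ch}_{b.name}_cordance" for b in bands]
    for band in bands:
        cols += [f"{a}-{b}_{band.name}_pec" for a, b in channel_pairs(list(channels))]
    return cols
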