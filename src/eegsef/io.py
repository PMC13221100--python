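"""Readers and writers: recordings as EDF (read) or portable binary
matrix + JSON sidecar (read/write), and the pipeline's CSV/TSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording


def save_recording(rec: Recording, path) -> None:
    """Write a recording as ``<path>.npy`` plus ``<path>.json`` sidecar
    carrying the sampling rate and channel labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), rec.data)
    sidecar = {"fs_hz": rec.fs_hz, "channel_labels": list(rec.channel_labels)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path) -> Recording:
    """Load a recording written by :func:`save_recording`, or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    data = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Recording(data, float(sidecar["fs_hz"]), tuple(sidecar["channel_labels"]))


def save_epoched(ep, path) -> None:
    """Write an EpochedEEG as ``.npy`` + JSON sidecar (fs, labels, kept
    epoch indices)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), ep.data)
    sidecar = {"fs_hz": ep.fs_hz, "channel_labels": list(ep.channel_labels),
               "kept_epoch_indices": [int(i) for i in ep.kept_epoch_indices]}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epoched(path):
    from .containers import EpochedEEG

    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return EpochedEEG(data, float(sidecar["fs_hz"]),
                      tuple(sidecar["channel_labels"]),
                      np.asarray(sidecar["kept_epoch_indices"], int))


def read_edf(path, channels=None) -> Recording:
    """Read a standard EDF recording (requires mne), in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names))


def write_events_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_feature_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index_label="subject_id")


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_clinical_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
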