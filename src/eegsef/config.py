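"""Pipeline configuration: one YAML file, one master seed.

Defaults encode the analysis conventions used throughout: 0.5-50 Hz
band-pass, 5-s epochs, 1-30 Hz Morlet grid with 7 cycles, 6x
factor-of-median event threshold, delta/theta 2-5 / alpha 6-14 / beta
15-29 Hz bands, k=2 KNN imputation, stratified 3-fold CV with a 2/3-1/3
outer split, and 5000 permutations. Per-stage random streams are derived
from the single master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .containers import Band

_BAND_DEFAULTS = {"delta_theta": (2.0, 5.0), "alpha": (6.0, 14.0), "beta": (15.0, 29.0)}


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips through YAML unchanged."""

    # synthetic cohort
    n_subjects: int = 82
    n_epochs: int = 71
    epoch_s: float = 5.0
    fs_hz: float = 250.0
    seed: int = 0
    # preprocessing
    filter_low_hz: float = 0.5
    filter_high_hz: float = 50.0
    reject_amp_uv: float = 150.0
    reject_kurt_z: float = 5.0
    # TFR / events
    freq_min_hz: float = 1.0
    freq_max_hz: float = 30.0
    n_cycles: float = 7.0
    decim: int = 5
    event_threshold_fom: float = 6.0
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in _BAND_DEFAULTS.items()})
    # model
    feature_set: str = "sef"
    alphas: list = field(default_factory=lambda: [0.1, 0.3, 1.0, 3.0, 10.0])
    l1_ratios: list = field(default_factory=lambda: [0.1, 0.5, 0.9])
    fit_intercept_options: list = field(default_factory=lambda: [True, False])
    n_splits: int = 3
    test_size: float = 1.0 / 3.0
    knn_k: int = 2
    n_perm: int = 5000
    # posthoc
    correction: str = "bonferroni"
    importance_cutoff: float = 1.5
    top_k: int = 5

    def band_objects(self):
        bands = []
        for name, (lo, hi) in self.bands.items():
            if name not in _BAND_DEFAULTS:
                raise ValueError(
                    f"unknown band name {name!r}; expected one of {list(_BAND_DEFAULTS)}"
                )
            bands.append(Band(name, float(lo), float(hi)))
        return tuple(bands)

    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_min_hz, self.freq_max_hz + 0.5)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        import zlib

        ss = np.random.SeedSequence([int(self.seed), zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.band_objects()  # validate band names early
        return cfg
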