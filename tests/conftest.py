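"""Shared fixtures: small synthetic subjects and cohorts, generated once
per session. All randomness is fixed-seeded."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from eegsef import PipelineConfig
from eegsef.pipeline import extract_subject_features
from eegsef.preprocess import preprocess_recording
from eegsef.synthetic import CohortSpec, simulate_recording
from eegsef.tfr import compute_tfr, normalize_fom

logging.getLogger("eegsef").setLevel(logging.ERROR)
logging.getLogger("eegsef.tfr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A light cohort spec: default bursts, 20 epochs."""
    return CohortSpec(n_subjects=2, n_epochs=20, seed=123)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    """(recording, truth) for one default-burst subject, 20 epochs."""
    return simulate_recording(small_spec, 0)


@pytest.fixture(scope="session")
def small_ntfr(small_subject):
    """Normalised TFR of Fp1 for the small subject (decim 5)."""
    rec, _ = small_subject
    ep = preprocess_recording(rec)
    tfr = compute_tfr(ep, ["Fp1"], decim=5)["Fp1"]
    return normalize_fom(tfr), ep


@pytest.fixture(scope="session")
def small_features(small_spec, default_cfg):
    """SEF series + events for the small subject via the standard path."""
    rec, truth = simulate_recording(small_spec, 0)
    sef, apf, events, n_epochs = extract_subject_features(
        rec, default_cfg, "S000", want_apf=True
    )
    return {"sef": sef, "apf": apf, "events": events,
            "n_epochs": n_epochs, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
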