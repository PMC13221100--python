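"""End-to-end orchestration: simulate -> preprocess -> extract features ->
fit -> post-hoc, with a reproducibility manifest.

`extract_subject_features` is the single path from a raw recording to the
per-subject SEF/APF vectors used everywhere (tests, acceptance runs,
CLI), so every consumer sees identical conventions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import pandas as pd

from . import io as eio
from .config import PipelineConfig
from .containers import Recording
from .events import aggregate_sef, detect_events_multi, events_to_frame, sef_columns
from .power import aggregate_apf
from .predict import ElasticNetResponseModel, assemble_features, permutation_test
from .preprocess import preprocess_recording
from .posthoc import channel_level_correlations, permutation_importance
from .synthetic import Cohort, CohortSpec, simulate_cohort
from .tfr import compute_tfr, normalize_fom

log = logging.getLogger(__name__)


def extract_subject_features(
    rec: Recording,
    cfg: PipelineConfig = None,
    subject_id=None,
    want_apf: bool = None,
):
    """Per-subject SEF (and optionally APF) from a continuous recording.

    Returns ``(sef, apf, events, n_epochs)`` where ``sef``/``apf`` are
    Series named by the subject and ``apf`` is None unless requested (or
    the config's feature set needs it).
    """
    cfg = cfg or PipelineConfig()
    if want_apf is None:
        want_apf = cfg.feature_set in ("apf", "both")
    bands = cfg.band_objects()
    ep = preprocess_recording(
        rec, cfg.filter_low_hz, cfg.filter_high_hz, cfg.epoch_s,
        cfg.reject_amp_uv, cfg.reject_kurt_z,
    )
    tfrs = compute_tfr(ep, freqs_hz=cfg.freqs(), n_cycles=cfg.n_cycles, decim=cfg.decim)
    events = []
    for ch in ep.channel_labels:
        ntfr = normalize_fom(tfrs[ch])
        events.extend(detect_events_multi(ntfr, bands, cfg.event_threshold_fom))
    sef = aggregate_sef(events, ep.n_epochs, ep.channel_labels, bands, subject_id)
    apf = None
    if want_apf:
        apf = aggregate_apf(tfrs, ep, bands, subject_id)
    return sef, apf, events, ep.n_epochs


def extract_cohort_features(recordings, subject_ids, cfg: PipelineConfig = None,
                            want_apf: bool = None):
    """SEF/APF tables (subjects x features) for a list of recordings."""
    cfg = cfg or PipelineConfig()
    sef_rows, apf_rows, ev_frames = [], [], []
    for sid, rec in zip(subject_ids, recordings):
        sef, apf, events, _ = extract_subject_features(rec, cfg, sid, want_apf)
        sef_rows.append(sef)
        if apf is not None:
            apf_rows.append(apf)
        ef = events_to_frame(events)
        ef.insert(0, "subject", sid)
        ev_frames.append(ef)
    sef_df = pd.DataFrame(sef_rows)
    sef_df = sef_df[sef_columns(recordings[0].channel_labels, cfg.band_objects())]
    apf_df = pd.DataFrame(apf_rows) if apf_rows else None
    return sef_df, apf_df, pd.concat(ev_frames, ignore_index=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute the full synthetic-cohort pipeline into ``out_dir``.

    Stages: simulate, preprocess+extract, fit, permutation test, post-hoc.
    Writes per-stage tables, a fitted-model JSON and a manifest with the
    config and SHA-256 checksums of every output; identical configs
    reproduce identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        spec = CohortSpec(
            n_subjects=cfg.n_subjects, n_epochs=cfg.n_epochs, epoch_s=cfg.epoch_s,
            fs_hz=cfg.fs_hz, seed=cfg.stage_seed("simulate"),
        )
        cohort: Cohort = simulate_cohort(spec)
        eio.write_clinical_csv(cohort.clinical, out / "clinical.csv")
        eio.write_events_tsv(cohort.ground_truth, out / "ground_truth_bursts.tsv")

        stage = "extract"
        sef_df, apf_df, events = extract_cohort_features(
            cohort.recordings, cohort.clinical["subject_id"], cfg
        )
        eio.write_feature_csv(sef_df, out / "sef.csv")
        if apf_df is not None:
            eio.write_feature_csv(apf_df, out / "apf.csv")
        eio.write_events_tsv(events, out / "events.tsv")

        stage = "fit"
        X, y = assemble_features(sef_df, apf_df, cohort.clinical, cfg.feature_set)
        model = ElasticNetResponseModel(
            alphas=tuple(cfg.alphas), l1_ratios=tuple(cfg.l1_ratios),
            fit_intercept_options=tuple(cfg.fit_intercept_options),
            n_splits=cfg.n_splits, test_size=cfg.test_size, n_neighbors=cfg.knn_k,
            random_state=cfg.stage_seed("fit"),
        ).fit(X, y)

        stage = "permutation"
        perm = permutation_test(model, n_permutations=cfg.n_perm,
                                random_state=cfg.stage_seed("perm"))

        stage = "posthoc"
        imp = permutation_importance(
            model, X.iloc[model.train_index_], y.iloc[model.train_index_],
            importance_cutoff=cfg.importance_cutoff, top_k=cfg.top_k,
            random_state=cfg.stage_seed("posthoc"),
        )
        imp.to_csv(out / "importance.csv", index=False)
        top_sef = [f for f in imp[imp.top_k].feature if f != "hamd_pre"]
        corr = channel_level_correlations(top_sef, X, y, correction=cfg.correction)
        corr.to_csv(out / "channel_correlations.csv", index=False)

        report = model.report_.to_dict()
        report["permutation"] = {
            "p_train": perm["p_train"], "p_test": perm["p_test"],
            "observed_train": perm["observed_train"],
            "observed_test": perm["observed_test"],
        }
        (out / "model.json").write_text(json.dumps(report, indent=1, default=float))
        model.predictions_.to_csv(out / "predictions.csv", index_label="row")
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfg.to_yaml(out / "config.yaml")
    manifest = {
        "config_sha256": _sha256(out / "config.yaml"),
        "seed": cfg.seed,
        "python": platform.python_version(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.name not in ("manifest.json",)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline complete: %s", out)
    return out
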