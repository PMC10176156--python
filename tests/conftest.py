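"""Shared fixtures: study-scale synthetic cohorts, computed once per session.

The default motor cohort targets ~200 analysable recordings with the
generator's default noise structure (subject offset SD 0.6 mo, session
offset SD 0.85 mo); the tracking cohort emphasizes repeat recordings for
longitudinal pair analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import motorchart as mc


def cohort_to_dataset(cohort: mc.MotorCohort, tag: str = "SYN") -> mc.DAPDataset:
    """Truth-playtime features for every analysable recording of a cohort."""
    rows, X = [], []
    for rec in mc.cohort_sessions(cohort):
        sel = mc.select_analysis_frames(rec)
        if sel.excluded:
            continue
        feats = mc.compute_features(sel.frames, recording_id=rec.recording_id)
        X.append(mc.flatten_features(feats))
        rows.append((rec.recording_id, rec.subject_id, rec.age_months))
    rows = pd.DataFrame(rows, columns=["recording_id", "subject_id", "age_months"])
    return mc.DAPDataset(
        X=np.vstack(X),
        ages=rows["age_months"].to_numpy(),
        subject_ids=rows["subject_id"].to_numpy(),
        recording_ids=rows["recording_id"].to_numpy(),
        tag=tag,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default-config motor cohort truncated to 200 recordings."""
    config = mc.SyntheticConfig(n_subjects=60, seed=7)
    cohort, truth = mc.generate_motor_cohort(config)
    manifest = cohort.manifest.iloc[:200].reset_index(drop=True)
    streams = {r: cohort.streams[r] for r in manifest["recording_id"]}
    return mc.MotorCohort(manifest=manifest, streams=streams), truth, config


@pytest.fixture(scope="session")
def default_dataset(default_cohort) -> mc.DAPDataset:
    cohort, _, _ = default_cohort
    return cohort_to_dataset(cohort)


@pytest.fixture(scope="session")
def loso_results(default_dataset) -> pd.DataFrame:
    """Leave-one-subject-out DAP for the default cohort."""
    return mc.loso_cv(default_dataset, seed=0)


@pytest.fixture(scope="session")
def dap_model(default_dataset) -> mc.DAPModel:
    """A single DAP model trained on the full default cohort."""
    return mc.fit_dap(default_dataset, seed=0)


@pytest.fixture(scope="session")
def tracking_cohort():
    """Longitudinal cohort: every subject has 2-7 recordings."""
    config = mc.SyntheticConfig(
        n_subjects=70, recordings_per_subject=(2, 7),
        session_hours={"mean": 3.0, "sd": 1.0, "min": 2.0, "max": 6.0},
        dataset_tag="TRK", seed=11,
    )
    cohort, truth = mc.generate_motor_cohort(config)
    return cohort, truth, config


@pytest.fixture(scope="session")
def tracking_dap(tracking_cohort, dap_model) -> pd.DataFrame:
    """Tracking-cohort DAP scored by the default-cohort model."""
    cohort, _, _ = tracking_cohort
    ds = cohort_to_dataset(cohort, tag="TRK")
    res = mc.predict_dap(dap_model, ds.X, recording_ids=ds.recording_ids)
    res["subject_id"] = ds.subject_ids
    res["age_months"] = ds.ages
    return res
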