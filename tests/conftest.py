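"""Shared fixtures: small synthetic cohorts reused across test modules.

Cohorts are generated once per session at reduced scale (60-s or shorter
recordings at 500 Hz) so the whole suite stays fast while exercising the
real pipeline.
"""

import numpy as np
import pandas as pd
import pytest

import eegmdd as em
from eegmdd import classify as clf
from eegmdd import pipeline as pl


def cohort_metadata(cohort) -> pd.DataFrame:
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(m) for _, m in cohort])


@pytest.fixture(scope="session")
def clean_subject():
    """One artifact-free 60-s subject at 500 Hz (no downsampling needed)."""
    cfg = em.CohortConfig(n_per_group=1, duration_s=60.0, fs=500.0,
                          artifact_rate=0.0, seed=101)
    return cfg, em.generate_subject(cfg, "HC", 0)


@pytest.fixture(scope="session")
def clean_epochs(clean_subject):
    _, rec = clean_subject
    return em.preprocess_recording(rec, target_fs=500.0)


@pytest.fixture(scope="session")
def recovery_study():
    """n=15/group cohort with the default planted effects; 60-s recordings.

    The full recovery protocol (cohort -> features -> group stats -> feature
    sets) computed once and shared across test modules.
    """
    from eegmdd import protocols

    return protocols.recovery_study(seed=11)


@pytest.fixture(scope="session")
def recovery_config(recovery_study):
    return recovery_study["config"]


@pytest.fixture(scope="session")
def recovery_features(recovery_study):
    return recovery_study["features"], recovery_study["metadata"]


@pytest.fixture(scope="session")
def recovery_sets(recovery_study):
    return recovery_study["sets"]


@pytest.fixture(scope="session")
def null_cohort_features():
    """All-null cohort (no planted effects): 10/group, 40-s recordings."""
    cfg = em.CohortConfig(
        n_per_group=10, duration_s=40.0, fs=500.0, artifact_rate=0.0,
        band_effects={"HC": {}, "MDD": {}},
        coupling_effects={"HC": {}, "MDD": {}},
        seed=77,
    )
    cohort = em.generate_cohort(cfg)
    pcfg = pl.PipelineConfig(cohort=cfg, seed=77)
    feats = pl.compute_features(cohort, pcfg)
    return feats, cohort_metadata(cohort)


@pytest.fixture(scope="session")
def null_sets(null_cohort_features):
    feats, meta = null_cohort_features
    groups = meta.set_index("subject_id")["group"]
    return clf.build_feature_sets(feats["power_epoch"], feats["conn_epoch"], groups)


def make_tone_recording(freqs_uv, fs=500.0, duration_s=10.0, n_channels=3, phase=0.0):
    """Recording whose channels all carry the same sum of sinusoids."""
    t = np.arange(int(duration_s * fs)) / fs
    sig = sum(a * np.sin(2 * np.pi * f * t + phase) for f, a in freqs_uv)
    data = np.tile(sig, (n_channels, 1))
    names = list(em.montage.CHANNELS[:n_channels])
    return em.Recording(subject_id="tone", channels=names, fs=fs, signal=data)
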