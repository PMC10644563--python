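"""Canned study protocols at desk scale.

These functions bundle the full analysis chain into reproducible experiments
on synthetic cohorts: the planted-effect recovery study, the LP-alpha
attribution study, and the all-null calibration study. They are used by the
acceptance checks and the examples; each is a pure function of its seed.

Problem sizes default to a reduced scale (15 subjects per group, 60-s
recordings at 500 Hz) so a study runs in tens of seconds; the planted effects
are calibrated to be detectable at exactly this scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import classify as clf
from . import pipeline as pl
from . import stats, synth
from .attribution import rank_features
from .connectivity import pair_feature_name, region_pairs


def _metadata_frame(cohort) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for _, m in cohort])


def recovery_study(
    seed: int,
    n_per_group: int = 15,
    duration_s: float = 60.0,
    fs: float = 500.0,
) -> dict:
    """Generate a default-effects cohort, run the full feature + stats chain.

    Returns the group-test tables, epoch-level feature sets and metadata.
    """
    cohort_cfg = synth.CohortConfig(
        n_per_group=n_per_group, duration_s=duration_s, fs=fs, seed=seed
    )
    cohort = synth.generate_cohort(cohort_cfg)
    cfg = pl.PipelineConfig(cohort=cohort_cfg, seed=seed)
    feats = pl.compute_features(cohort, cfg)
    meta = _metadata_frame(cohort)
    groups = meta.set_index("subject_id")["group"]
    power_tests = stats.ttest_features(feats["power_subject"], groups)
    conn_tests = stats.ttest_features(feats["conn_subject"], groups)
    sets = clf.build_feature_sets(feats["power_epoch"], feats["conn_epoch"], groups)
    return {
        "config": cohort_cfg, "features": feats, "metadata": meta,
        "power_tests": power_tests, "conn_tests": conn_tests, "sets": sets,
    }


def recovery_pattern_holds(power_tests: pd.DataFrame, conn_tests: pd.DataFrame,
                           cohort_cfg: synth.CohortConfig) -> bool:
    """Does the analysis reproduce the planted qualitative group pattern?

    Checks, after BH-FDR: negative t (MDD higher) for occipital delta and
    right-occipital theta relative power; positive t (MDD lower) for
    occipital alpha; planted alpha region pairs with weaker coupling in MDD
    (t > 0, majority significant) and planted gamma pairs stronger in MDD
    (t < 0, majority significant).
    """
    def sig_neg(f):
        return power_tests.loc[f, "t"] < 0 and power_tests.loc[f, "p_fdr"] < 0.05

    def sig_pos(f):
        return power_tests.loc[f, "t"] > 0 and power_tests.loc[f, "p_fdr"] < 0.05

    ok = (sig_neg("RO-delta") and sig_neg("LO-delta") and sig_neg("RO-theta")
          and sig_pos("RO-alpha") and sig_pos("LO-alpha"))

    def planted_names(band):
        # resolve each planted pair to its canonical feature-name order
        names = []
        for a, b in cohort_cfg.coupling_effects["HC"].get(band, {}):
            for ca, cb in region_pairs():
                if {ca, cb} == {a, b}:
                    names.append(pair_feature_name(ca, cb, band))
        return names

    for band, sign in (("alpha", 1), ("gamma", -1)):
        names = planted_names(band)
        t = conn_tests.loc[names, "t"] * sign
        sig = conn_tests.loc[names, "significant"]
        ok = ok and (t > 0).all() and sig.sum() >= (len(names) + 1) // 2
    return bool(ok)


def lp_alpha_attribution_study(
    seed: int,
    n_per_group: int = 10,
    duration_s: float = 40.0,
    fs: float = 500.0,
    n_draws: int = 100,
) -> dict:
    """Cohort whose strongest planted effect is left-parietal alpha; returns
    the Shapley ranking of the band-power feature set and the local-accuracy
    error of the report."""
    cohort_cfg = synth.CohortConfig(
        n_per_group=n_per_group, duration_s=duration_s, fs=fs,
        artifact_rate=0.0, seed=seed,
        band_effects={"HC": {}, "MDD": {"alpha": {"left_parietal": 0.5}}},
        coupling_effects={"HC": {}, "MDD": {}},
    )
    cohort = synth.generate_cohort(cohort_cfg)
    cfg = pl.PipelineConfig(
        cohort=cohort_cfg, seed=seed,
        attribution=pl.AttributionConfig(n_background=60, n_explain=12,
                                         n_draws=n_draws),
    )
    feats = pl.compute_features(cohort, cfg)
    meta = _metadata_frame(cohort)
    groups = meta.set_index("subject_id")["group"]
    sets = clf.build_feature_sets(feats["power_epoch"], feats["conn_epoch"], groups)
    result = pl.explain_model(sets, cfg)
    report = result["report"]
    return {
        "ranking": result["ranking"],
        "top_feature": result["ranking"][0],
        "local_accuracy_max_error": float(report.local_accuracy_error().max()),
        "report": report,
    }


def null_calibration_study(
    null_set: clf.FeatureSet,
    seed: int,
    n_runs: int = 50,
    permutations: int = 50,
    selector: str = "PCA",
    model: str = "KNN",
) -> dict:
    """Permutation-test calibration on an effect-free feature set.

    Each run relabels subjects at random (a draw from the null), evaluates the
    model once, and runs a B-permutation test; the resulting p-values should
    be approximately uniform and the accuracies near chance.
    """
    rng = np.random.default_rng(seed)
    cfg = clf.HarnessConfig(repeats=2, permutations=permutations,
                            seed=int(rng.integers(2**31)))
    ps, accs = [], []
    for _ in range(n_runs):
        y_null = clf._permute_labels_by_subject(null_set, rng)
        fs_null = clf.FeatureSet(null_set.id, null_set.X, null_set.feature_names,
                                 null_set.subjects, y_null)
        obs = clf._fit_eval_once(fs_null, selector, model, cfg,
                                 int(rng.integers(2**31)))["accuracy"]
        run_cfg = dataclasses.replace(cfg, seed=int(rng.integers(2**31)))
        p, _ = clf.permutation_test(fs_null, selector, model, run_cfg,
                                    observed_accuracy=obs)
        ps.append(p)
        accs.append(obs)
    return {"p_values": np.array(ps), "accuracies": np.array(accs)}
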