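"""End-to-end pipeline: synthesize -> preprocess -> features -> stats ->
classify -> explain, with a YAML-serializable configuration and a manifest
recording every output file's content hash so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from . import classify as clf
from . import connectivity, spectral, stats, synth
from .preprocess import preprocess_recording

log = logging.getLogger("eegmdd")


@dataclass
class AttributionConfig:
    feature_set: str = "set1"
    selector: str = "PCA"
    model: str = "KNN"
    n_background: int = 100
    n_explain: int = 20
    n_draws: int = 100
    top_k: int = 20


@dataclass
class PipelineConfig:
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    # preprocessing
    band: tuple[float, float] = (0.1, 80.0)
    notch: tuple[float, float] = (49.0, 51.0)
    target_fs: float = 500.0
    epoch_length_s: float = 2.0
    reject_uv: float = 80.0
    # harness
    harness: clf.HarnessConfig = field(default_factory=clf.HarnessConfig)
    grid: list[tuple[str, str, str]] = field(
        default_factory=lambda: [("set1", "PCA", "KNN")]
    )
    with_permutation: bool = False
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    out_dir: str | None = None
    write_edf: bool = False
    seed: int = 0

    def __post_init__(self):
        # one root seed drives every stage
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.harness = dataclasses.replace(self.harness, seed=self.seed)


# ---------------------------------------------------------------- YAML I/O

def _pairs_to_str(coupling: dict) -> dict:
    return {
        g: {b: {f"{a}|{c}": v for (a, c), v in pairs.items()} for b, pairs in bands.items()}
        for g, bands in coupling.items()
    }


def _pairs_from_str(coupling: dict) -> dict:
    return {
        g: {b: {tuple(k.split("|")): v for k, v in pairs.items()} for b, pairs in bands.items()}
        for g, bands in coupling.items()
    }


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cohort"]["channel_set"] = list(cfg.cohort.channel_set)
    d["cohort"]["coupling_effects"] = _pairs_to_str(cfg.cohort.coupling_effects)
    d["band"], d["notch"] = list(cfg.band), list(cfg.notch)
    d["grid"] = [list(g) for g in cfg.grid]
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    ch = dict(d.pop("cohort", {}))
    if "coupling_effects" in ch:
        ch["coupling_effects"] = _pairs_from_str(ch["coupling_effects"])
    if "channel_set" in ch:
        ch["channel_set"] = tuple(ch["channel_set"])
    hd = dict(d.pop("harness", {}))
    ad = dict(d.pop("attribution", {}))
    if "band" in d:
        d["band"] = tuple(d["band"])
    if "notch" in d:
        d["notch"] = tuple(d["notch"])
    if "grid" in d:
        d["grid"] = [tuple(g) for g in d["grid"]]
    return PipelineConfig(
        cohort=synth.CohortConfig(**ch),
        harness=clf.HarnessConfig(**hd),
        attribution=AttributionConfig(**ad),
        **d,
    )


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------- stages

def compute_features(cohort, cfg: PipelineConfig):
    """Preprocess every subject and build epoch- and subject-level tables."""
    power_epoch, conn_epoch, conn_subject, rejections = [], [], [], {}
    for rec, meta in cohort:
        ep = preprocess_recording(
            rec, band=cfg.band, notch=cfg.notch, target_fs=cfg.target_fs,
            epoch_length_s=cfg.epoch_length_s, reject_uv=cfg.reject_uv,
        )
        n_total = int(rec.duration_s // cfg.epoch_length_s)
        rejections[meta.subject_id] = n_total - ep.n_epochs
        power_epoch.append(spectral.roi_relative_power(ep))
        conn_epoch.append(connectivity.epoch_wpli_features(ep))
        conn_subject.append(connectivity.subject_wpli_features(ep))
        log.info("preprocessed %s: %d/%d epochs kept", meta.subject_id, ep.n_epochs, n_total)
    power_epoch = pd.concat(power_epoch)
    conn_epoch = pd.concat(conn_epoch)
    conn_subject = pd.DataFrame(conn_subject)
    conn_subject.index.name = "subject_id"
    power_subject = spectral.subject_aggregate(power_epoch)
    return {
        "power_epoch": power_epoch,
        "power_subject": power_subject,
        "conn_epoch": conn_epoch,
        "conn_subject": conn_subject,
        "rejections": rejections,
    }


def run_group_stats(features: dict, metadata: pd.DataFrame) -> dict:
    groups = metadata.set_index("subject_id")["group"]
    power_tests = stats.ttest_features(features["power_subject"], groups)
    conn_tests = stats.ttest_features(features["conn_subject"], groups)
    sex_counts = pd.crosstab(metadata["group"], metadata["sex"]).to_numpy()
    chi2, chi2_p = stats.chi2_sex(sex_counts)
    mdd = metadata[metadata["group"] == "MDD"].set_index("subject_id")
    corr = stats.correlate_clinical(
        features["power_subject"].loc[mdd.index], mdd["hamd17"]
    )
    return {
        "power_tests": power_tests,
        "conn_tests": conn_tests,
        "sex_chi2": {"chi2": chi2, "p": chi2_p},
        "hamd_correlations": corr,
    }


def explain_model(sets: dict, cfg: PipelineConfig) -> dict:
    """Fit the configured pipeline on one grouped split and attribute the
    positive-class score over held-out samples, in original feature space."""
    a = cfg.attribution
    fs = sets[a.feature_set]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    tr, te = clf.split(fs, cfg.harness, int(rng.integers(2**31)))
    from sklearn.preprocessing import StandardScaler

    scaler = StandardScaler().fit(fs.X[tr])
    sel, Xtr, _ = clf.select_features(
        scaler.transform(fs.X[tr]), fs.y[tr], scaler.transform(fs.X[te]),
        a.selector, cfg.harness, seed=cfg.seed,
    )
    model = clf.make_model(a.model, seed=cfg.seed)
    model.fit(Xtr, fs.y[tr])

    def score_fn(X):
        return clf._score_samples(model, sel.transform(scaler.transform(X)))

    bg_idx = rng.choice(tr, size=min(a.n_background, len(tr)), replace=False)
    ex_idx = rng.choice(te, size=min(a.n_explain, len(te)), replace=False)
    report = attr.shapley_values(
        score_fn, fs.X[ex_idx], fs.X[bg_idx], n_draws=a.n_draws,
        seed=int(rng.integers(2**31)), feature_names=fs.feature_names,
    )
    ranking = attr.rank_features(report, top_k=min(a.top_k, len(fs.feature_names)))
    return {"report": report, "ranking": ranking}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the results bundle and (optionally) writes
    CSV outputs plus a manifest with content hashes under ``cfg.out_dir``."""
    stage = "synth"
    try:
        cohort = synth.generate_cohort(cfg.cohort)
        metadata = pd.DataFrame(
            [dataclasses.asdict(m) for _, m in cohort]
        )
        stage = "preprocess/features"
        features = compute_features(cohort, cfg)
        stage = "stats"
        group_stats = run_group_stats(features, metadata)
        stage = "classify"
        groups = metadata.set_index("subject_id")["group"]
        sets = clf.build_feature_sets(features["power_epoch"], features["conn_epoch"], groups)
        results = []
        for sid, sel, mdl in cfg.grid:
            res = clf.train_eval(sets[sid], sel, mdl, cfg.harness)
            if cfg.with_permutation:
                res.permutation_p, _ = clf.permutation_test(
                    sets[sid], sel, mdl, cfg.harness,
                    observed_accuracy=res.metrics["accuracy"][0],
                )
            results.append(res)
            log.info("classified %s/%s/%s: acc=%.3f", sid, sel, mdl, res.metrics["accuracy"][0])
        stage = "attribution"
        explanation = explain_model(sets, cfg)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    bundle = {
        "metadata": metadata,
        "features": features,
        "stats": group_stats,
        "classification": clf.results_table(results),
        "classification_results": results,
        "attribution_ranking": explanation["ranking"],
        "attribution_report": explanation["report"],
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if cfg.write_edf:
            from .edf import write_edf

            (out / "edf").mkdir(exist_ok=True)
            for rec, meta in cohort:
                write_edf(out / "edf" / f"{meta.subject_id}.edf", rec)
        files = {
            "metadata.csv": metadata,
            "power_subject.csv": features["power_subject"],
            "wpli_subject.csv": features["conn_subject"],
            "stats_power.csv": group_stats["power_tests"],
            "stats_wpli.csv": group_stats["conn_tests"],
            "hamd_correlations.csv": group_stats["hamd_correlations"],
            "classification.csv": bundle["classification"],
            "attribution_rank.csv": pd.DataFrame(
                {"rank": range(1, len(explanation["ranking"]) + 1),
                 "feature": explanation["ranking"]}
            ),
        }
        for name, df in files.items():
            df.to_csv(out / name)
        manifest = {
            "config": config_to_dict(cfg),
            "epochs_rejected": features["rejections"],
            "sex_chi2": group_stats["sex_chi2"],
            "outputs": {name: _sha256(out / name) for name in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        bundle["manifest"] = manifest
    return bundle
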