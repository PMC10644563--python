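"""Epoch-level classification harness.

Three feature sets (relative band power, region-pair wPLI, their
concatenation) are benchmarked over a grid of feature selectors (SVM-RFE,
L1-penalized logistic regression, PCA) and classifiers (decision tree, RBF
SVM, gradient-boosted trees, Gaussian naive Bayes, k-nearest neighbours).
Every repeat draws a fresh 90/10 split; under the default subject-grouped
policy no participant contributes epochs to both partitions, which is the
leakage-safe reading of participant-based stratification. Standardization
and feature selection are fitted on training rows only.

Significance of the observed mean accuracy is assessed with a label
permutation test at the subject level: p = (b + 1)/(B + 1), so a model that
beats all B = 100 permutations reports p = 1/101 ≈ 0.0099.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import accuracy_score, precision_score, recall_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

POSITIVE_CLASS = "MDD"
SELECTORS = ("SVM-RFE", "LASSO-L1", "PCA", "none")
MODELS = ("DT", "SVM", "GBDT", "NB", "KNN")
FEATURE_SET_IDS = ("set1", "set2", "set3")


@dataclass
class FeatureSet:
    """Samples = epochs; every sample maps to exactly one subject."""

    id: str
    X: np.ndarray
    feature_names: list[str]
    subjects: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.subjects = np.asarray(self.subjects)
        self.y = np.asarray(self.y)
        n = self.X.shape[0]
        if not (len(self.subjects) == len(self.y) == n):
            raise ValueError("row/label/subject misalignment")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature-name count mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class HarnessConfig:
    train_fraction: float = 0.9
    repeats: int = 10
    permutations: int = 100
    split_policy: str = "subject-grouped"  # or "epoch-stratified" (leakage-prone)
    seed: int = 0
    rfe_cv: int = 3
    rfe_step: int = 1
    lasso_Cs: int = 5
    lasso_cv: int = 3
    pca_variance: float = 0.95

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.split_policy not in ("subject-grouped", "epoch-stratified"):
            raise ValueError(f"unknown split policy {self.split_policy!r}")


@dataclass
class ClassificationResult:
    """One grid cell: metric means ± sd over repeats, plus permutation p."""

    feature_set: str
    selector: str
    model: str
    metrics: dict[str, tuple[float, float]]  # name -> (mean, sd)
    per_repeat: pd.DataFrame
    permutation_p: float | None = None
    notes: list[str] = field(default_factory=list)

    def table_row(self) -> dict:
        def fmt(name):
            m, s = self.metrics[name]
            return f"{m:.3f} ± {s:.3f}"

        row = {
            "feature_set": self.feature_set, "selector": self.selector, "model": self.model,
            "Accuracy": fmt("accuracy"), "Precision": fmt("precision"),
            "Recall": fmt("recall"), "AUC": fmt("auc"),
        }
        if self.permutation_p is not None:
            row["p-value"] = f"{self.permutation_p:.4f}"
        return row


def build_feature_sets(
    power_epoch: pd.DataFrame,
    conn_epoch: pd.DataFrame,
    groups_by_subject: pd.Series,
) -> dict[str, FeatureSet]:
    """Assemble the three epoch-level feature sets, row-aligned by (subject, epoch)."""
    if not power_epoch.index.equals(conn_epoch.index):
        if set(power_epoch.index) != set(conn_epoch.index):
            raise ValueError("power and connectivity tables cover different epochs")
        conn_epoch = conn_epoch.loc[power_epoch.index]
    subjects = power_epoch.index.get_level_values("subject_id").to_numpy()
    y = groups_by_subject.loc[subjects].to_numpy()
    sets = {}
    combined = pd.concat([power_epoch, conn_epoch], axis=1)
    for sid, table in (("set1", power_epoch), ("set2", conn_epoch), ("set3", combined)):
        sets[sid] = FeatureSet(
            id=sid, X=table.to_numpy(float), feature_names=list(table.columns),
            subjects=subjects, y=y,
        )
    return sets


def split(
    fs: FeatureSet, cfg: HarnessConfig, repeat_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test row indices for one repeat.

    subject-grouped: whole subjects are assigned to one partition, the test
    set taking ~(1 - train_fraction) of each class's subjects (at least one).
    epoch-stratified: rows are split irrespective of subject (replicates the
    leakage-prone reading; subjects may straddle partitions).
    """
    rng = np.random.default_rng(repeat_seed)
    n = fs.n_samples
    if cfg.split_policy == "epoch-stratified":
        test_idx = []
        for label in np.unique(fs.y):
            rows = np.flatnonzero(fs.y == label)
            rng.shuffle(rows)
            k = max(1, int(round(len(rows) * (1 - cfg.train_fraction))))
            test_idx.append(rows[:k])
        test = np.sort(np.concatenate(test_idx))
    else:
        labels = np.unique(fs.y)
        per_class = {}
        for label in labels:
            subj = np.unique(fs.subjects[fs.y == label])
            if len(subj) < 2:
                raise ValueError(f"need >= 2 subjects in class {label!r} to split")
            rng.shuffle(subj)
            per_class[label] = subj
        # largest-remainder allocation of test subjects across classes keeps
        # the overall test share at (1 - train_fraction) within one subject
        # while preserving class proportions within +/-1 subject
        exact = np.array([len(per_class[lb]) * (1 - cfg.train_fraction)
                          for lb in labels])
        k = np.floor(exact).astype(int)
        total = max(int(round(exact.sum())), len(labels))
        order = np.argsort(-(exact - np.floor(exact) + 1e-9 * rng.random(len(labels))))
        i = 0
        while k.sum() < total and i < 10 * len(labels):
            j = order[i % len(labels)]
            if k[j] < len(per_class[labels[j]]) - 1:
                k[j] += 1
            i += 1
        k = np.minimum(np.maximum(k, 1),
                       [len(per_class[lb]) - 1 for lb in labels])
        test_subjects = [s for lb, kk in zip(labels, k)
                         for s in per_class[lb][:kk]]
        test = np.flatnonzero(np.isin(fs.subjects, test_subjects))
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    return np.flatnonzero(mask), test


class _LassoSelector:
    """Keep features with nonzero L1-logistic coefficients at a CV-chosen penalty.

    On signal-free data (e.g. label-permuted runs of the permutation test)
    every CV score ties at chance and the strongest penalty wins, zeroing all
    coefficients; in that case the selector falls back to the weakest penalty
    in the grid so downstream models still receive features. Only if even
    that leaves nothing (degenerate input) does it raise.
    """

    def __init__(self, Cs: int, cv: int, seed: int):
        self._seed = seed
        self._est = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
            random_state=seed, max_iter=2000,
        )
        self.support_: np.ndarray | None = None

    def fit(self, X, y):
        self._est.fit(X, y)
        self.support_ = np.abs(self._est.coef_[0]) > 1e-12
        if not self.support_.any():
            from sklearn.linear_model import LogisticRegression

            weak = LogisticRegression(
                penalty="l1", solver="liblinear", C=float(np.max(self._est.Cs_)),
                random_state=self._seed, max_iter=2000,
            ).fit(X, y)
            self.support_ = np.abs(weak.coef_[0]) > 1e-12
        if not self.support_.any():
            raise ValueError("LASSO-L1 eliminated every feature")
        return self

    def transform(self, X):
        return X[:, self.support_]


class _RfeSelector:
    """SVM-RFE: recursive elimination by linear-SVM weights, CV-chosen count."""

    def __init__(self, step: int, cv: int, seed: int):
        self._est = RFECV(
            LinearSVC(C=1.0, dual=False, max_iter=5000, random_state=seed),
            step=step, cv=cv, scoring="accuracy", min_features_to_select=1,
        )

    def fit(self, X, y):
        self._est.fit(X, y)
        return self

    @property
    def support_(self):
        return self._est.support_

    def transform(self, X):
        return self._est.transform(X)


class _Identity:
    def fit(self, X, y):
        return self

    def transform(self, X):
        return X


def make_selector(method: str, cfg: HarnessConfig, seed: int):
    if method == "SVM-RFE":
        return _RfeSelector(cfg.rfe_step, cfg.rfe_cv, seed)
    if method == "LASSO-L1":
        return _LassoSelector(cfg.lasso_Cs, cfg.lasso_cv, seed)
    if method == "PCA":
        return PCA(n_components=cfg.pca_variance, svd_solver="full", random_state=seed)
    if method == "none":
        return _Identity()
    raise ValueError(f"unknown selector {method!r}")


def make_model(name: str, seed: int):
    if name == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if name == "GBDT":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed
        )
    if name == "NB":
        return GaussianNB()
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown model {name!r}")


def select_features(X_train, y_train, X_test, method: str, cfg: HarnessConfig, seed: int = 0):
    """Fit a selector on training rows only and transform both partitions."""
    sel = make_selector(method, cfg, seed)
    sel.fit(X_train, y_train)
    Xtr, Xte = sel.transform(X_train), sel.transform(X_test)
    if Xtr.shape[1] == 0:
        raise ValueError(f"{method} eliminated every feature")
    return sel, Xtr, Xte


def _score_samples(model, X) -> np.ndarray:
    """Continuous positive-class score for AUC."""
    if hasattr(model, "predict_proba"):
        classes = list(model.classes_)
        return model.predict_proba(X)[:, classes.index(POSITIVE_CLASS)]
    s = model.decision_function(X)
    return s if model.classes_[1] == POSITIVE_CLASS else -s


def _fit_eval_once(fs: FeatureSet, selector: str, model_name: str,
                   cfg: HarnessConfig, repeat_seed: int,
                   y_override: np.ndarray | None = None) -> dict:
    """One split -> standardize -> select -> fit -> test metrics."""
    y = fs.y if y_override is None else y_override
    for attempt in range(20):
        tr, te = split(fs, cfg, repeat_seed + 1000 * attempt)
        if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
            break
    else:
        raise RuntimeError("could not draw a two-class split in 20 attempts")
    scaler = StandardScaler().fit(fs.X[tr])
    Xtr, Xte = scaler.transform(fs.X[tr]), scaler.transform(fs.X[te])
    _, Xtr, Xte = select_features(Xtr, y[tr], Xte, selector, cfg, seed=repeat_seed)
    model = make_model(model_name, seed=repeat_seed)
    model.fit(Xtr, y[tr])
    pred = model.predict(Xte)
    score = _score_samples(model, Xte)
    y_true = y[te]
    return {
        "accuracy": accuracy_score(y_true, pred),
        "precision": precision_score(y_true, pred, pos_label=POSITIVE_CLASS, zero_division=0),
        "recall": recall_score(y_true, pred, pos_label=POSITIVE_CLASS, zero_division=0),
        "auc": roc_auc_score((y_true == POSITIVE_CLASS).astype(int), score),
        "n_train": len(tr), "n_test": len(te), "resample_attempts": attempt,
    }


def train_eval(fs: FeatureSet, selector: str, model_name: str, cfg: HarnessConfig) -> ClassificationResult:
    """Mean ± sd of accuracy/precision/recall/AUC over repeated splits."""
    if cfg.repeats < 2:
        raise ValueError("need >= 2 repeats for a standard deviation")
    ss = np.random.SeedSequence([cfg.seed, _combo_tag(fs.id, selector, model_name)])
    seeds = [int(s) for s in ss.generate_state(cfg.repeats)]
    rows = [_fit_eval_once(fs, selector, model_name, cfg, s) for s in seeds]
    per_repeat = pd.DataFrame(rows)
    metrics = {
        m: (float(per_repeat[m].mean()), float(per_repeat[m].std(ddof=1)))
        for m in ("accuracy", "precision", "recall", "auc")
    }
    notes = []
    n_res = int(per_repeat["resample_attempts"].sum())
    if n_res:
        notes.append(f"{n_res} single-class splits resampled")
    return ClassificationResult(fs.id, selector, model_name, metrics, per_repeat, notes=notes)


def _combo_tag(*parts: str) -> int:
    import zlib

    return zlib.crc32("/".join(parts).encode()) % (2**31)


def _permute_labels_by_subject(fs: FeatureSet, rng: np.random.Generator) -> np.ndarray:
    """Shuffle group labels across subjects (keeping group sizes)."""
    subj, first = np.unique(fs.subjects, return_index=True)
    labels = fs.y[first]
    perm = rng.permutation(labels)
    lut = dict(zip(subj, perm))
    return np.array([lut[s] for s in fs.subjects])


def permutation_test(
    fs: FeatureSet,
    selector: str,
    model_name: str,
    cfg: HarnessConfig,
    observed_accuracy: float | None = None,
) -> tuple[float, np.ndarray]:
    """Label-permutation significance of the observed mean accuracy.

    Labels are permuted at the subject level (all of a subject's epochs move
    together), matching the grouped split. The statistic must be exchangeable
    under the null, so every permutation is evaluated exactly like the
    observed value: mean accuracy over ``cfg.repeats`` fresh splits. Returns
    (p, permuted statistics) with p = (b + 1)/(B + 1), b = number of permuted
    runs >= observed.
    """
    if observed_accuracy is None:
        observed_accuracy = train_eval(fs, selector, model_name, cfg).metrics["accuracy"][0]
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _combo_tag("perm", fs.id, selector, model_name)])
    )
    null = np.empty(cfg.permutations)
    for b in range(cfg.permutations):
        y_perm = _permute_labels_by_subject(fs, rng)
        accs = [
            _fit_eval_once(fs, selector, model_name, cfg,
                           int(rng.integers(2**31)), y_override=y_perm)["accuracy"]
            for _ in range(cfg.repeats)
        ]
        null[b] = float(np.mean(accs))
    b_ge = int((null >= observed_accuracy).sum())
    p = (b_ge + 1) / (cfg.permutations + 1)
    return p, null


def run_grid(
    sets: dict[str, FeatureSet],
    cfg: HarnessConfig,
    selectors=("SVM-RFE", "LASSO-L1", "PCA"),
    models=MODELS,
    with_permutation: bool = False,
) -> list[ClassificationResult]:
    """Evaluate every (feature set, selector, model) cell of the grid."""
    results = []
    for sid, fs in sets.items():
        for sel in selectors:
            for mdl in models:
                res = train_eval(fs, sel, mdl, cfg)
                if with_permutation:
                    res.permutation_p, _ = permutation_test(
                        fs, sel, mdl, cfg, observed_accuracy=res.metrics["accuracy"][0]
                    )
                results.append(res)
    return results


def results_table(results: list[ClassificationResult]) -> pd.DataFrame:
    """Benchmark table: one row per grid cell, metrics as ``mean ± sd``."""
    return pd.DataFrame([r.table_row() for r in results])
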