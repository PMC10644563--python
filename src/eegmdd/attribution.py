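"""Model-agnostic Shapley-value feature attribution.

Shapley values are estimated by Monte-Carlo sampling of feature orderings
with background-set marginalization: for each random permutation of the
features and each background row, features are switched one at a time from
the background value to the explained sample's value, and the change in the
model score is credited to the switched feature. Averaging over orderings
gives the Shapley value of each feature in units of the score.

The estimator satisfies local accuracy *exactly* (up to float rounding):
because every ordering walk starts at a background row and ends at the
explained sample, the per-sample attributions sum to
``score(x) - mean(score(background rows used))`` for any number of draws.

Attributions are computed in the original feature space — any scaler,
selector or projection belongs inside the explained score function — so a
ranking like "LP-alpha first" refers to interpretable features rather than
principal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AttributionReport:
    """Per-(sample, feature) Shapley values and the shared base value."""

    values: np.ndarray  # (n_samples, n_features), units of the model score
    base_value: float
    feature_names: list[str]
    scores: np.ndarray  # score(x) for each explained sample

    def mean_abs(self) -> pd.Series:
        """Global importance: mean |Shapley value| per feature."""
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=self.feature_names
        ).rename("mean_abs_shap")

    def local_accuracy_error(self) -> np.ndarray:
        """|base + sum(values) - score| per sample; ~float epsilon by construction."""
        return np.abs(self.base_value + self.values.sum(axis=1) - self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def shapley_values(
    score_fn,
    samples: np.ndarray,
    background: np.ndarray,
    n_draws: int = 200,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> AttributionReport:
    """Monte-Carlo permutation-sampling Shapley values.

    Parameters
    ----------
    score_fn : callable mapping (n, d) arrays to (n,) scores (e.g. the
        positive-class probability of a fitted pipeline).
    samples : (n_samples, d) rows to explain.
    background : (n_background, d) reference rows; marginalized features take
        their values from here. Draw ``d % n_background`` cycles the rows so
        all samples share the same background sequence and the local-accuracy
        identity is exact.
    n_draws : feature orderings per sample.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    n_samples, d = samples.shape
    if background.shape[1] != d:
        raise ValueError("background feature count differs from samples")
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(d)]
    if len(names) != d:
        raise ValueError("feature_names length mismatch")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(d) for _ in range(n_draws)])
    bg_rows = background[np.arange(n_draws) % background.shape[0]]  # (n_draws, d)
    base_value = float(np.mean(score_fn(bg_rows)))

    values = np.zeros((n_samples, d))
    scores = np.empty(n_samples)
    for s in range(n_samples):
        x = samples[s]
        # hybrids[:, k] = background with the first k features of the
        # permutation switched to x; k = 0..d inclusive.
        hybrids = np.repeat(bg_rows[:, None, :], d + 1, axis=1)  # (draws, d+1, d)
        for k in range(d):
            feat = perms[:, k]
            rows = np.arange(n_draws)
            hybrids[rows[:, None], np.arange(k + 1, d + 1)[None, :], feat[:, None]] = x[feat][:, None]
        out = np.asarray(score_fn(hybrids.reshape(-1, d)), dtype=float)
        if out.shape != (n_draws * (d + 1),):
            raise ValueError("score_fn must return exactly one score per input row")
        out = out.reshape(n_draws, d + 1)
        deltas = np.diff(out, axis=1)  # (draws, d): contribution of perms[:, k]
        phi = np.zeros(d)
        np.add.at(phi, perms.ravel(), deltas.ravel())
        values[s] = phi / n_draws
        scores[s] = out[0, d]  # fully switched-in row == score(x)
    return AttributionReport(values=values, base_value=base_value,
                             feature_names=list(names), scores=scores)


def rank_features(report: AttributionReport, top_k: int | None = None) -> list[str]:
    """Features ordered by descending mean |Shapley value|.

    Ties are broken lexicographically by feature name so the ordering is
    deterministic.
    """
    imp = report.mean_abs()
    if top_k is not None and top_k > len(imp):
        raise ValueError("top_k exceeds the feature count")
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return order[: top_k if top_k is not None else len(order)]
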