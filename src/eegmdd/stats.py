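"""Group-difference and clinical-correlation statistics.

Subject-level features (relative power per ROI x band, or region-pair wPLI
per band) are compared between groups with two-tailed two-sample t-tests and
Benjamini-Hochberg FDR adjustment within the feature family passed in. The
sign convention is t > 0 when the healthy-control mean exceeds the patient
mean (HC - MDD), so a planted patient increase shows up as a negative t.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests


def ttest_features(
    features: pd.DataFrame,
    groups: pd.Series,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-tailed two-sample t-test with BH-FDR adjustment.

    Parameters
    ----------
    features : subject-level feature matrix (rows = subjects).
    groups : "MDD"/"HC" label per subject (index-aligned with features).
    equal_var : pooled-variance Student's t by default; False gives Welch.

    The FDR family is the full set of columns passed in (40 for the power
    table, 140 for connectivity). Features with zero variance in both groups
    are flagged and assigned p = 1.
    """
    groups = groups.loc[features.index]
    is_mdd = (groups == "MDD").to_numpy()
    is_hc = (groups == "HC").to_numpy()
    if is_mdd.sum() < 2 or is_hc.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    x_hc = features.loc[is_hc].to_numpy(float)
    x_mdd = features.loc[is_mdd].to_numpy(float)

    rows = []
    for j, name in enumerate(features.columns):
        hc, mdd = x_hc[:, j], x_mdd[:, j]
        degenerate = hc.std(ddof=1) == 0 and mdd.std(ddof=1) == 0
        if degenerate:
            t, p = 0.0, 1.0
        else:
            t, p = sst.ttest_ind(hc, mdd, equal_var=equal_var)
        rows.append(
            {
                "feature": name,
                "mean_hc": hc.mean(), "sd_hc": hc.std(ddof=1),
                "mean_mdd": mdd.mean(), "sd_mdd": mdd.std(ddof=1),
                "t": float(t), "p": float(p),
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    rej, p_fdr, _, _ = multipletests(out["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    out["p_fdr"] = p_fdr
    out["significant"] = rej
    out["direction"] = np.sign(out["mean_hc"] - out["mean_mdd"]).astype(int)
    return out


def chi2_sex(counts) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 sex table."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the contingency table")
    chi2, p, dof, _ = sst.chi2_contingency(counts, correction=False)
    assert dof == 1
    return float(chi2), float(p)


def correlate_clinical(features: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Pearson r (and two-tailed p) between each feature and a clinical score.

    Intended for the patient group only (controls have no severity score).
    Constant features are flagged with r = NaN.
    """
    scores = scores.loc[features.index].to_numpy(float)
    if len(scores) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(float)
        if np.std(x) == 0 or np.std(scores) == 0:
            rows.append({"feature": name, "r": np.nan, "p": np.nan, "constant": True})
            continue
        r, p = sst.pearsonr(x, scores)
        rows.append({"feature": name, "r": float(r), "p": float(p), "constant": False})
    return pd.DataFrame(rows).set_index("feature")
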