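"""Explain a fitted pipeline with Monte-Carlo Shapley values.

The score function wraps the whole pipeline (scaler -> PCA -> KNN positive-
class probability), so attributions land on the interpretable band-power
features rather than principal components. Local accuracy (base value plus
attributions equals the model score) holds exactly for this estimator.
"""

from eegmdd import protocols

out = protocols.lp_alpha_attribution_study(seed=5)

print("top 10 features by mean |Shapley value|:")
for rank, name in enumerate(out["ranking"][:10], 1):
    print(f"  {rank:2d}. {name}")
print(f"\nlocal accuracy max error: {out['local_accuracy_max_error']:.2e}")

# The cohort's strongest planted effect is reduced left-parietal alpha in
# patients, and LP-alpha duly tops the ranking; the remaining LP bands follow
# because relative power is normalized within each ROI.
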