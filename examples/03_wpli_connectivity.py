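"""Weighted phase lag index: planted coupling vs. independent channels.

wPLI = |E[Im S]| / E[|Im S|] over observations of the cross-spectrum S.
A quarter-cycle lagged shared source gives wPLI near 1; independent noise
shrinks toward 0 as observations accumulate; zero-lag (volume-conducted)
copies give exactly 0.
"""

import eegmdd as em

pair = ("left_occipital", "right_occipital")
cfg = em.CohortConfig(
    n_per_group=1, duration_s=120.0, fs=500.0, artifact_rate=0.0, seed=2,
    coupling_effects={"HC": {"alpha": {pair: 0.8}}, "MDD": {}},
)
rec = em.generate_subject(cfg, "HC", 0)
epochs = em.preprocess_recording(rec, target_fs=500.0)

alpha = [b for b in em.DEFAULT_BANDS if b.name == "alpha"][0]
mat = em.wpli_matrix(epochs, alpha)
agg = em.connectivity.region_aggregate(mat, epochs.channels)

print(f"alpha wPLI, planted pair {pair}: {agg.loc[pair]:.3f}")
others = [agg.loc[a, b] for a, b in em.connectivity.region_pairs()
          if {a, b} != set(pair)]
print(f"alpha wPLI, mean of the other 27 region pairs: {sum(others)/len(others):.3f}")

# The planted occipital coupling stands far above the uncoupled background,
# which reflects only estimator bias at this epoch count.
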