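"""Estimate individual ancestry and choose the number of clusters.

`select_k` fits the admixture model over a range of K with replicated
holdout cross-entropy and applies a one-standard-error rule; `fit_ancestry`
refits at the chosen K and the Q matrix can be aligned to any reference
labelling for comparison.
"""

import numpy as np

from adaptscan import ancestry, geno
from adaptscan.simdata import SimConfig, simulate

ds = simulate(SimConfig(seed=2, fst=0.3, n_snps=1500))
G = geno.filter_variants(ds.genotypes)

k, scores = ancestry.select_k(G, k_range=range(1, 7), seed=5, n_reps=3)
print("chosen K:", k)
print(scores.round(4))

model = ancestry.fit_ancestry(G, k, seed=11, n_reps=5)
Qa = ancestry.align_clusters(model.Q, ds.q_true)
print(f"\nmean |Q_hat - Q_true| = {np.abs(Qa - ds.q_true).mean():.3f}")

labels = ancestry.assign_clusters(model.Q, threshold=0.70)
n_admixed = int(np.sum(labels == -1))
print(f"{n_admixed} individuals are admixed at the 0.70 threshold")

# ancestry-aware imputation of missing genotypes
G_imputed = ancestry.impute_ancestry(G, model)
print("missing after imputation:", int(np.isnan(G_imputed.dosage).sum()))
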