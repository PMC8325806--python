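"""Drive the two association scans by hand and combine their candidates.

This mirrors what `run_full` does internally, exposing the intermediate
objects: latent factors, per-variable z-scores with genomic-control
calibration, RDA loadings with permutation-tested axes, and the combined
candidate bookkeeping.
"""

import numpy as np
import pandas as pd

from adaptscan import ancestry, geno, lfmm, rda
from adaptscan.envpheno import EnvPhenoTables, env_pca, expand_to_individuals, predictor_table
from adaptscan.pipeline import DEFAULT_PRIORITY, combine_candidates
from adaptscan.simdata import SimConfig, simulate

ds = simulate(SimConfig(seed=3))
G = geno.ld_prune(geno.snp_density_filter(geno.filter_variants(ds.genotypes)))

# structure: ancestry model, ancestry-aware imputation, latent factors
model = ancestry.fit_ancestry(G, 3, seed=10, n_reps=3)
Gc = ancestry.impute_ancestry(G, model).dosage
U = lfmm.fit_latent_factors(Gc, 2)

# per-individual predictor table: geography, climate PCs, phenotypes
tables = EnvPhenoTables(env=ds.sites.env, geo=ds.sites.sites,
                        pheno=ds.pheno.drop(columns=["L"]))
pca = env_pca(tables.env)
vt = predictor_table(tables, pca, n_pcs=3)
prov = G.samples["provenance"]
V = pd.DataFrame({c: expand_to_individuals(vt[c], prov) for c in vt.columns})

# latent-factor scans, one variable at a time
scans = []
for name in V.columns:
    res = lfmm.scan_variable(Gc, V[name].to_numpy(), U, name, G.locus_ids())
    print(f"{name:<10s} lambda={res.inflation:.3f} "
          f"candidates={int(res.candidate.sum())}")
    scans.append(res)
lfmm_cands = lfmm.candidate_list(scans)

# redundancy analysis with collinearity prescreen and permutation-tested axes
Xk, dropped = rda.prescreen_predictors(V, r_max=0.7, priority=list(DEFAULT_PRIORITY))
Gr = geno.impute_major(G).dosage
m = rda.fit_rda(Gr, Xk.to_numpy(), predictor_names=list(Xk.columns))
axis_p = rda.anova_axes(m, Gr, Xk.to_numpy(), n_perm=199, seed=0, max_axes=2)
n_axes = max(min(int(np.sum(np.nan_to_num(axis_p, nan=1.0) <= 0.05)), 2), 1)
out = rda.detect_outliers(m, n_axes=n_axes, sd_mult=3.0, locus_ids=G.locus_ids())
out = rda.assign_predictor(out, Gr, Xk, G.locus_ids())
print(f"\nRDA adj R^2 = {m.adj_r2:.3f}, {len(out.table)} outliers "
      f"on {n_axes} axis/axes")

combined = combine_candidates(lfmm_cands, out, None, G)
print("union:", len(combined["union"]),
      " intersection:", len(combined["intersection"]))
print("per class:", combined["per_class_counts"])
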