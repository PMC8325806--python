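"""Run the whole analysis in one call and read the report.

`run_full` chains every stage: environmental PCA, variant filtering and LD
pruning, gene annotation, ancestry estimation (with automatic choice of K),
latent-factor association scans across geography / climate PCs / phenotypes,
redundancy analysis with permutation tests, candidate combination, variance
partitioning, polygenic scores and the heterozygosity regression.
"""

import json
from pathlib import Path

from adaptscan.pipeline import RunConfig, make_report, run_full
from adaptscan.simdata import SimConfig, simulate, write_dataset

ds = simulate(SimConfig(seed=1))
out = Path("example_dataset")
write_dataset(ds, out)

bundle = run_full(
    ds.genotypes, ds.sites.sites, ds.sites.env, ds.pheno.drop(columns=["L"]),
    config=RunConfig(seed=1),
    gene_models_path=out / "gene_models.gff3",
)

report = make_report(bundle)
print(json.dumps({k: report[k] for k in
                  ("mean_he", "k_selected", "n_loci_analyzed")}, indent=2))
print("LFMM candidates:", report["lfmm"]["n_candidates"])
print("RDA outliers:   ", report["rda"]["n_outliers"])
print("union:          ", report["combined"]["n_union"])
print("\nVariance partition of the candidate loci:")
for row in report["partition"]:
    print(f"  {row['model']:<40s} {row['percentage']:7.2f}%  p={row['p']}")
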