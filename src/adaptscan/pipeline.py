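"""End-to-end orchestration: filtering, structure, association scans, RDA,
candidate bookkeeping, variance partitioning and polygenic scores.

``run_full`` wires the stages together on in-memory objects (use
``simdata.simulate`` or ``simdata.read_dataset`` to obtain inputs) and
returns a result bundle; ``combine_candidates`` and ``make_report`` handle
the cross-method accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, envpheno, geno, lfmm, partition, polyscore, rda

GEO_VARS = ("longitude", "latitude", "altitude")
PHENO_VARS = ("spring", "autumn", "height", "survival")

#: collinearity prescreen keep-order: climate PC1 wins over longitude,
#: altitude over latitude and PC2
DEFAULT_PRIORITY = ["PC1", "altitude", "PC3", "spring", "autumn", "height",
                    "survival", "longitude", "latitude", "PC2"]


@dataclass
class RunConfig:
    maf: float = 0.05
    max_missing: float = 0.25
    min_depth: int = 10
    min_bp_per_snp: float = 10.0
    r2_prune: float = 0.5
    r_prescreen: float = 0.7
    sd_mult: float = 3.0
    fdr: float = 0.01
    p_cut: float = 0.001
    n_perm_global: int = 1000
    n_perm_partition: int = 999
    k_range: tuple[int, int] = (1, 10)
    k_reps: int = 3
    nmf_reps: int = 5
    flank: int = 500
    proximity_bp: int = 150
    n_pcs: int = 3
    max_outlier_axes: int = 2
    cluster_threshold: float = 0.70
    seed: int = 0
    skip_select_k: bool = False
    fixed_k: int | None = None

    def stage_seed(self, stage: str) -> int:
        # stable per-stage fan-out so stages can be rerun in isolation
        h = sum((i + 1) * ord(c) for i, c in enumerate(stage))
        return (self.seed * 100003 + h) % (2**31)


def _variable_table(tables, pca, n_pcs):
    return envpheno.predictor_table(tables, pca, n_pcs=n_pcs)


def run_full(
    G: geno.GenotypeMatrix,
    sites: pd.DataFrame,
    env: pd.DataFrame,
    pheno: pd.DataFrame,
    config: RunConfig | None = None,
    gene_models_path=None,
) -> dict:
    """Execute the whole analysis; returns a result bundle (dict).

    Inputs: a genotype matrix whose samples map to provenances, plus
    provenance-level geography, environment and phenotype tables.
    """
    cfg = config or RunConfig()
    bundle: dict = {"config": asdict(cfg), "log": []}

    prov = G.samples["provenance"]
    missing = set(prov) - set(sites.index)
    if missing:
        raise ValueError(f"samples with unknown provenance: {sorted(missing)[:5]}")

    tables = envpheno.EnvPhenoTables(env=env, geo=sites, pheno=pheno)

    # --- environmental PCA -------------------------------------------------
    pca = envpheno.env_pca(tables.env)
    bundle["pca"] = pca
    bundle["log"].append(
        f"PCA: first {cfg.n_pcs} components explain "
        f"{100 * pca.explained[: cfg.n_pcs].sum():.2f}% of environmental variance"
    )

    # --- genotype filtering ------------------------------------------------
    filter_log: list = []
    G1 = geno.filter_variants(
        G, min_depth=cfg.min_depth, maf=cfg.maf, max_missing=cfg.max_missing,
        log=filter_log,
    )
    G1 = geno.snp_density_filter(G1, min_bp_per_snp=cfg.min_bp_per_snp)
    G1 = geno.ld_prune(G1, r2_max=cfg.r2_prune)
    bundle["filter_log"] = filter_log
    bundle["log"].append(f"filtering: {G.n_loci} -> {G1.n_loci} loci")

    annotation = None
    if gene_models_path is not None:
        annotation = geno.annotate_snps(G1, gene_models_path, flank=cfg.flank)
        bundle["annotation"] = annotation

    he, mean_he = geno.expected_heterozygosity(G1)
    bundle["mean_he"] = mean_he

    # --- ancestry ----------------------------------------------------------
    if cfg.fixed_k is not None:
        k_star, profile = cfg.fixed_k, None
    else:
        k_star, profile = ancestry.select_k(
            G1, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            seed=cfg.stage_seed("ancestry"), n_reps=cfg.k_reps,
        )
    model = ancestry.fit_ancestry(
        G1, k_star, seed=cfg.stage_seed("ancestry-fit"), n_reps=cfg.nmf_reps
    )
    labels = ancestry.assign_clusters(model.Q, threshold=cfg.cluster_threshold)
    bundle.update(k_star=k_star, k_profile=profile, ancestry=model, cluster_labels=labels)

    # --- variables expanded to individuals ---------------------------------
    var_table = _variable_table(tables, pca, cfg.n_pcs)
    scan_vars = [*GEO_VARS, *var_table.columns[3:3 + cfg.n_pcs], *PHENO_VARS]
    V = pd.DataFrame(
        {
            name: envpheno.expand_to_individuals(var_table[name], prov)
            for name in scan_vars
        }
    )
    bundle["individual_variables"] = V

    # --- latent-factor association scan ------------------------------------
    G_lfmm = ancestry.impute_ancestry(G1, model)
    # K ancestry clusters span K-1 dimensions after column centering (the
    # rows of Q sum to one), so K-1 latent factors absorb the structure
    # without soaking up additional axes of genuine signal.
    n_factors = max(k_star - 1, 1)
    U = lfmm.fit_latent_factors(G_lfmm.dosage, n_factors)
    scans = [
        lfmm.scan_variable(
            G_lfmm.dosage, V[name].to_numpy(), U, name, G1.locus_ids(),
            fdr=cfg.fdr, p_cut=cfg.p_cut,
        )
        for name in scan_vars
    ]
    lfmm_candidates = lfmm.candidate_list(scans)
    bundle.update(lfmm_scans=scans, lfmm_candidates=lfmm_candidates)

    # --- global RDA ---------------------------------------------------------
    X_kept, drops = rda.prescreen_predictors(
        V, r_max=cfg.r_prescreen, priority=DEFAULT_PRIORITY
    )
    bundle["prescreen_dropped"] = drops
    G_rda = geno.impute_major(G1)
    m = rda.fit_rda(G_rda.dosage, X_kept.to_numpy(), predictor_names=list(X_kept.columns))
    rda.anova_global(m, G_rda.dosage, X_kept.to_numpy(),
                     n_perm=cfg.n_perm_global, seed=cfg.stage_seed("rda"))
    axis_p = rda.anova_axes(m, G_rda.dosage, X_kept.to_numpy(),
                            n_perm=cfg.n_perm_global, seed=cfg.stage_seed("rda-axes"),
                            max_axes=cfg.max_outlier_axes)
    n_sig = int(np.sum(np.nan_to_num(axis_p, nan=1.0) <= 0.05))
    n_axes = max(min(n_sig, cfg.max_outlier_axes), 1)
    outliers = rda.detect_outliers(
        m, n_axes=n_axes, sd_mult=cfg.sd_mult, locus_ids=G_rda.locus_ids()
    )
    outliers = rda.assign_predictor(outliers, G_rda.dosage, X_kept, G_rda.locus_ids())
    bundle.update(rda_model=m, rda_outliers=outliers, rda_n_axes=n_axes)

    # --- regional RDA per cluster -------------------------------------------
    regional = {}
    for k in range(k_star):
        res = rda.regional_rda(
            G1, labels, k, V,
            n_perm=cfg.n_perm_global, seed=cfg.stage_seed(f"rda-k{k}"),
            sd_mult=cfg.sd_mult, n_axes=cfg.max_outlier_axes,
            r_max=cfg.r_prescreen, priority=DEFAULT_PRIORITY,
        )
        regional[k] = res
        if isinstance(res[1], str):
            bundle["log"].append(f"cluster {k}: {res[1]}")
    bundle["regional"] = regional

    # --- combine ------------------------------------------------------------
    combined = combine_candidates(
        lfmm_candidates, outliers, annotation, G1,
        proximity_bp=cfg.proximity_bp,
    )
    bundle["combined"] = combined

    # --- variance partitioning ----------------------------------------------
    union_ids = combined["union"]
    if union_ids:
        idx = [G_rda.locus_ids().get_loc(l) for l in sorted(union_ids)]
        Yc = G_rda.dosage[:, idx]
        geo_block = V[[c for c in GEO_VARS if c in X_kept.columns]]
        clim_block = V[[c for c in X_kept.columns if c.startswith("PC")]]
        ph_block = V[list(PHENO_VARS)]
        if geo_block.shape[1] and clim_block.shape[1]:
            part = partition.variance_partition(
                Yc, geo_block, clim_block, ph_block,
                n_perm=cfg.n_perm_partition, seed=cfg.stage_seed("partition"),
            )
            bundle["partition"] = part

        # --- polygenic scores ------------------------------------------------
        scores_by_var = {}
        for name in scan_vars:
            fav = polyscore.polarize_alleles(
                G1.dosage[:, idx], V[name].to_numpy(), [G1.locus_ids()[j] for j in idx]
            )
            scores_by_var[name] = polyscore.polygenic_scores(
                G1.dosage[:, idx], fav, [G1.locus_ids()[j] for j in idx]
            )
        bundle["polygenic_scores"] = scores_by_var
        bundle["trend_table"] = polyscore.trend_table(scores_by_var, V[scan_vars])

        het = geno.individual_heterozygosity(G1, idx)
        ok = np.isfinite(het)
        fit, kept_vars = polyscore.het_env_regression(het[ok], V.loc[ok, scan_vars])
        bundle["het_regression"] = {"variables": kept_vars,
                                    "adj_r2": float(fit.rsquared_adj) if kept_vars else 0.0}
    else:
        bundle["log"].append("no candidates detected; downstream stages skipped")

    bundle["genotypes_filtered"] = G1
    return bundle


def combine_candidates(
    lfmm_candidates: pd.DataFrame,
    rda_outliers: rda.OutlierSet,
    annotation: geno.SnpAnnotation | None,
    G: geno.GenotypeMatrix,
    proximity_bp: int = 150,
) -> dict:
    """Cross-method bookkeeping at locus and gene level.

    Returns union/intersection locus sets, proximity pairs (same contig,
    within ``proximity_bp``), per-variable tallies and, when annotation is
    available, gene-level overlap counts.  Audits the inclusion-exclusion
    identity |union| = |lfmm| + |rda| - |intersection|.
    """
    lfmm_set = set(lfmm_candidates["locus_id"]) if len(lfmm_candidates) else set()
    rda_set = rda_outliers.locus_ids()
    union = lfmm_set | rda_set
    inter = lfmm_set & rda_set
    assert len(union) == len(lfmm_set) + len(rda_set) - len(inter)

    pos_of = {}
    ids = G.locus_ids()
    for j, lid in enumerate(ids):
        pos_of[lid] = (G.loci["contig"].iloc[j], int(G.loci["pos"].iloc[j]))
    proximity = []
    for a in sorted(lfmm_set - rda_set):
        ca, pa = pos_of.get(a, (None, None))
        for b in sorted(rda_set):
            cb, pb = pos_of.get(b, (None, None))
            if ca is not None and ca == cb and abs(pa - pb) <= proximity_bp:
                proximity.append((a, b, abs(pa - pb)))
                break

    per_variable: dict[str, set] = {}
    if len(lfmm_candidates):
        for v, sub in lfmm_candidates.groupby("variable"):
            per_variable.setdefault(v, set()).update(sub["locus_id"])
    for _, row in rda_outliers.table.iterrows():
        if row["predictor"] is not None:
            per_variable.setdefault(row["predictor"], set()).add(row["locus_id"])

    def _vclass(name):
        if name in GEO_VARS:
            return "geography"
        if str(name).startswith("PC"):
            return "climate"
        return "phenotype"

    per_class: dict[str, set] = {"geography": set(), "climate": set(), "phenotype": set()}
    for v, s in per_variable.items():
        per_class[_vclass(v)].update(s)

    out = {
        "lfmm": lfmm_set,
        "rda": rda_set,
        "union": union,
        "intersection": inter,
        "proximity_pairs": proximity,
        "per_variable": {v: sorted(s) for v, s in per_variable.items()},
        "per_class_counts": {c: len(s) for c, s in per_class.items()},
    }
    if annotation is not None:
        gene_of = annotation.gene_of()
        genes_lfmm = {gene_of.get(l) for l in lfmm_set} - {None}
        genes_rda = {gene_of.get(l) for l in rda_set} - {None}
        out["genes_lfmm"] = genes_lfmm
        out["genes_rda"] = genes_rda
        out["genes_union"] = genes_lfmm | genes_rda
        out["genes_both_methods"] = genes_lfmm & genes_rda
    return out


def make_report(bundle: dict) -> dict:
    """Machine-readable summary of a run (JSON-serializable)."""
    combined = bundle.get("combined", {})
    rep = {
        "mean_he": bundle.get("mean_he"),
        "k_selected": bundle.get("k_star"),
        "n_loci_analyzed": bundle["genotypes_filtered"].n_loci if "genotypes_filtered" in bundle else None,
        "lfmm": {
            "n_candidates": len(combined.get("lfmm", [])),
            "inflation": {s.variable: s.inflation for s in bundle.get("lfmm_scans", [])},
        },
        "rda": {
            "n_outliers": len(combined.get("rda", [])),
            "adj_r2": bundle["rda_model"].adj_r2 if "rda_model" in bundle else None,
            "global_p": bundle["rda_model"].global_p if "rda_model" in bundle else None,
            "axis_p": list(map(float, np.atleast_1d(bundle["rda_model"].axis_p)))
            if bundle.get("rda_model") is not None and bundle["rda_model"].axis_p is not None
            else None,
        },
        "combined": {
            "n_union": len(combined.get("union", [])),
            "n_intersection": len(combined.get("intersection", [])),
            "n_proximity_pairs": len(combined.get("proximity_pairs", [])),
            "per_class_counts": combined.get("per_class_counts", {}),
        },
        "log": bundle.get("log", []),
    }
    if "annotation" in bundle:
        rep["annotation_tally"] = bundle["annotation"].tally().to_dict()
    if "partition" in bundle:
        rep["partition"] = bundle["partition"].table.to_dict(orient="records")
    if "trend_table" in bundle:
        rep["trends"] = bundle["trend_table"].to_dict(orient="records")
    if "het_regression" in bundle:
        rep["het_regression"] = bundle["het_regression"]
    return rep


def write_report(bundle: dict, outdir) -> Path:
    """Write the JSON report plus key TSV tables under a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep = make_report(bundle)
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(rep, fh, indent=2, default=str)
    if "lfmm_candidates" in bundle and len(bundle["lfmm_candidates"]):
        bundle["lfmm_candidates"].to_csv(outdir / "lfmm_candidates.tsv", sep="\t", index=False)
    if "rda_outliers" in bundle:
        bundle["rda_outliers"].table.to_csv(outdir / "rda_outliers.tsv", sep="\t", index=False)
    if "partition" in bundle:
        bundle["partition"].table.to_csv(outdir / "partition.tsv", sep="\t", index=False)
    if "trend_table" in bundle:
        bundle["trend_table"].to_csv(outdir / "trends.tsv", sep="\t", index=False)
    return path
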