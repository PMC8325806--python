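"""Generator properties: determinism, round-trips, planted truth, He."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adaptscan import geno
from adaptscan.simdata import (
    InvalidConfigError,
    SimConfig,
    simulate,
    simulate_gene_models,
    simulate_phenotypes,
    simulate_sites,
    write_dataset,
    read_dataset,
)


def test_invalid_configs():
    with pytest.raises(InvalidConfigError):
        SimConfig(n_sites=0)
    with pytest.raises(InvalidConfigError):
        SimConfig(n_adaptive=100, n_snps=50)
    with pytest.raises(InvalidConfigError):
        SimConfig(fst=1.0)
    with pytest.raises(InvalidConfigError):
        SimConfig(n_sites=10, n_ind=5)


def test_deterministic_given_seed(small_cfg):
    a = simulate(small_cfg)
    b = simulate(small_cfg)
    np.testing.assert_array_equal(
        np.nan_to_num(a.genotypes.dosage, nan=-1),
        np.nan_to_num(b.genotypes.dosage, nan=-1),
    )
    pd.testing.assert_frame_equal(a.pheno, b.pheno)
    np.testing.assert_array_equal(a.q_true, b.q_true)


def test_sites_dimensions_and_geo_correlations():
    cfg = SimConfig(seed=3)
    sites = simulate_sites(cfg)
    assert sites.env.shape == (47, 19)
    assert not sites.env.isna().any().any()
    # geography tracks the latent factors negatively
    assert np.corrcoef(sites.sites["longitude"], sites.factors[:, 0])[0, 1] < -0.5
    assert np.corrcoef(sites.sites["latitude"], sites.factors[:, 2])[0, 1] < -0.5
    assert np.corrcoef(sites.sites["altitude"], sites.factors[:, 1])[0, 1] < -0.5


def test_env_pca_recovers_factors():
    from adaptscan.envpheno import env_pca

    cfg = SimConfig(seed=1)
    sites = simulate_sites(cfg)
    res = env_pca(sites.env)
    assert res.explained[:3].sum() >= 0.80


def test_truth_table_and_null_generator():
    cfg = SimConfig(n_sites=15, n_ind=40, n_snps=400, n_adaptive=0, seed=2)
    ds = simulate(cfg)
    assert not ds.truth["is_adaptive"].any()
    # mean He near the Balding-Nichols Monte-Carlo expectation
    rng = np.random.default_rng(0)
    p0 = np.clip(rng.beta(0.7, 0.7, size=100_000), 0.05, 0.95)
    a = p0 * (1 - cfg.fst) / cfg.fst
    b = (1 - p0) * (1 - cfg.fst) / cfg.fst
    f = rng.beta(a, b)
    he_expect = np.mean(2 * f * (1 - f))
    _, mean_he = geno.expected_heterozygosity(ds.genotypes)
    assert abs(mean_he - he_expect) < 0.05


def test_mean_he_near_029():
    ds = simulate(SimConfig(seed=4))
    _, mean_he = geno.expected_heterozygosity(ds.genotypes)
    assert 0.26 <= mean_he <= 0.32


def test_zero_slope_indistinguishable():
    cfg = SimConfig(n_sites=20, n_ind=60, n_snps=600, n_adaptive=60,
                    cline_slope=0.0, missing_rate=0.0, seed=5)
    ds = simulate(cfg)
    prov = ds.genotypes.samples["provenance"]
    site_of = {p: i for i, p in enumerate(ds.sites.sites.index)}
    driving = np.array([ds.sites.factors[site_of[p], cfg.driving_factor] for p in prov])
    ad = ds.truth["is_adaptive"].to_numpy()
    D = ds.genotypes.dosage
    rs = np.array([
        abs(np.corrcoef(D[:, j], driving)[0, 1]) if D[:, j].std() > 0 else 0.0
        for j in range(D.shape[1])
    ])
    ks = stats.ks_2samp(rs[ad], rs[~ad])
    assert ks.pvalue > 0.01


def test_planted_r_monotone_in_slope():
    means = []
    for slope in (0.3, 0.8, 1.5):
        cfg = SimConfig(n_sites=20, n_ind=60, n_snps=400, n_adaptive=40,
                        cline_slope=slope, missing_rate=0.0, seed=6)
        ds = simulate(cfg)
        prov = ds.genotypes.samples["provenance"]
        site_of = {p: i for i, p in enumerate(ds.sites.sites.index)}
        driving = np.array([ds.sites.factors[site_of[p], cfg.driving_factor] for p in prov])
        ad = ds.truth["is_adaptive"].to_numpy()
        D = ds.genotypes.dosage[:, ad]
        rs = [abs(np.corrcoef(D[:, j], driving)[0, 1]) for j in range(D.shape[1])]
        means.append(np.mean(rs))
    assert means[0] < means[1] < means[2]


def test_phenotype_noiseless_correlation():
    cfg = SimConfig(pheno_noise_sd=0.0, seed=7)
    sites = simulate_sites(cfg)
    pheno = simulate_phenotypes(cfg, sites)
    r = np.corrcoef(pheno["spring"], sites.factors[:, 0])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)
    # survival loads positively on the height channel
    assert np.corrcoef(pheno["survival"], pheno["height"])[0, 1] > 0


def test_phenotype_default_spring_correlation_band():
    rs = []
    for seed in range(1, 21):
        cfg = SimConfig(seed=seed)
        sites = simulate_sites(cfg)
        pheno = simulate_phenotypes(cfg, sites)
        rs.append(np.corrcoef(pheno["spring"], sites.factors[:, 0])[0, 1])
    assert 0.5 <= np.mean(rs) <= 0.9


def test_placement_roundtrip_exact(tmp_path, small_ds):
    from adaptscan.simdata import write_gff3

    gff = tmp_path / "gm.gff3"
    write_gff3(small_ds.gene_models, gff)
    ann = geno.annotate_snps(small_ds.genotypes, gff, flank=500)
    got = ann.table.set_index("locus_id")["primary"]
    want = small_ds.placement.set_index("locus_id")["category"]
    agree = (got.loc[want.index] == want).mean()
    assert agree == 1.0


def test_gene_models_containment(small_ds):
    gm = small_ds.gene_models
    genes = gm[gm["type"] == "gene"].set_index("feature_id")
    for _, r in gm[gm["type"] != "gene"].iterrows():
        g = genes.loc[r["parent"]]
        assert g["start"] <= r["start"] <= r["end"] <= g["end"]
    # CDS contained in an exon of the same gene
    exons = gm[gm["type"] == "exon"]
    for _, r in gm[gm["type"] == "CDS"].iterrows():
        ex = exons[exons["parent"] == r["parent"]]
        assert ((ex["start"] <= r["start"]) & (r["end"] <= ex["end"])).any()


def test_overlapping_exons_rejected(small_ds):
    from adaptscan.simdata import InvalidGeneModelError
    import json

    loci = small_ds.genotypes.loci.copy()
    first_gene = loci["_gene"].iloc[0]
    sub = loci["_gene"] == first_gene
    blocks = json.loads(loci.loc[sub, "_exon_blocks"].iloc[0])
    if len(blocks) < 2:
        blocks = [[100, 200], [150, 300]]
    else:
        blocks[1][0] = blocks[0][1] - 1  # force overlap
    loci.loc[sub, "_exon_blocks"] = json.dumps(blocks)
    with pytest.raises(InvalidGeneModelError):
        simulate_gene_models(small_ds.config, loci)


def test_dataset_roundtrip(tmp_path, small_ds):
    paths = write_dataset(small_ds, tmp_path / "ds")
    G, sites, env, pheno = read_dataset(tmp_path / "ds")
    A, B = small_ds.genotypes.dosage, G.dosage
    np.testing.assert_array_equal(np.isnan(A), np.isnan(B))
    np.testing.assert_array_equal(np.nan_to_num(A, nan=-1), np.nan_to_num(B, nan=-1))
    assert G.n_loci == small_ds.config.n_snps
    pd.testing.assert_frame_equal(sites, small_ds.sites.sites)
    pd.testing.assert_frame_equal(pheno, small_ds.pheno)
    assert (G.samples["provenance"] == small_ds.genotypes.samples["provenance"]).all()
    assert paths["manifest"].exists()


def test_vcf_shape_at_full_scale(tmp_path):
    ds = simulate(SimConfig(seed=0))
    paths = write_dataset(ds, tmp_path / "full")
    n_records = sum(
        1 for line in open(paths["vcf"]) if not line.startswith("#")
    )
    assert n_records == 2909
    header = next(l for l in open(paths["vcf"]) if l.startswith("#CHROM"))
    assert len(header.rstrip("\n").split("\t")) == 9 + 92
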