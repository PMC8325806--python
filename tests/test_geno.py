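"""VCF I/O, filtering, LD pruning, annotation, diversity, imputation."""

import numpy as np
import pandas as pd
import pytest

from adaptscan import geno
from adaptscan.geno import GenotypeMatrix

from conftest import make_flank_boundary_files


def _toy_matrix():
    dosage = np.array(
        [
            [0.0, 1.0, 2.0, np.nan],
            [1.0, 1.0, 0.0, 0.0],
            [2.0, 0.0, 0.0, 1.0],
            [0.0, 2.0, 2.0, 1.0],
        ]
    )
    loci = pd.DataFrame(
        {
            "contig": ["c1", "c1", "c2", "c2"],
            "pos": [10, 40, 10, 40],
            "ref": ["A"] * 4,
            "alt": ["G"] * 4,
            "locus_id": [f"L{i}" for i in range(4)],
        }
    )
    samples = pd.DataFrame(
        {"sample": [f"S{i}" for i in range(4)], "provenance": ["P1", "P1", "P2", "P2"]}
    )
    return GenotypeMatrix(dosage, loci, samples)


def test_vcf_read_basic(toy_vcf):
    G = geno.read_vcf(toy_vcf)
    assert G.n_individuals == 4 and G.n_loci == 8
    # v1: 0/0, 0/1, 1/1, 0/1 -> dosages 0,1,2,1
    np.testing.assert_array_equal(G.dosage[:, 0], [0, 1, 2, 1])
    # v4 has two missing genotypes
    assert np.isnan(G.dosage[0, 3]) and np.isnan(G.dosage[1, 3])
    assert G.contig_lengths == {"ctg1": 5000, "ctg2": 40}
    assert G.depth is not None and G.depth[3, 2] == 5


def test_vcf_roundtrip(tmp_path, toy_vcf):
    G = geno.read_vcf(toy_vcf)
    out = tmp_path / "rt.vcf"
    geno.write_vcf(G, out)
    G2 = geno.read_vcf(out)
    np.testing.assert_array_equal(np.isnan(G.dosage), np.isnan(G2.dosage))
    np.testing.assert_array_equal(
        np.nan_to_num(G.dosage, nan=-1), np.nan_to_num(G2.dosage, nan=-1)
    )
    pd.testing.assert_frame_equal(G.loci, G2.loci)


def test_filter_variants_counts(toy_vcf):
    G = geno.read_vcf(toy_vcf)
    log = []
    Gf = geno.filter_variants(G, min_depth=10, maf=0.05, max_missing=0.25, log=log)
    ids = set(Gf.locus_ids())
    # v3: depth 5 genotype masked -> freq 0 -> fails MAF; v6 monomorphic;
    # v4 has 50% missing -> fails missingness
    assert "v6" not in ids and "v4" not in ids and "v3" not in ids
    assert {"v1", "v2", "v5", "v7", "v8"} <= ids
    assert log[-1][0] == "combined"


def test_depth_masking():
    G = _toy_matrix()
    G.depth = np.full(G.dosage.shape, 50.0)
    G.depth[0, 0] = 3.0
    Gf = geno.filter_variants(G, min_depth=10, maf=0.0, max_missing=0.9)
    j = list(Gf.locus_ids()).index("L0")
    assert np.isnan(Gf.dosage[0, j])


def test_snp_density_filter(toy_vcf):
    G = geno.read_vcf(toy_vcf)
    # ctg2: 40 bp / 2 SNPs = 20 bp per SNP; dropped at threshold 25
    Gf = geno.snp_density_filter(G, min_bp_per_snp=25.0)
    assert set(Gf.loci["contig"]) == {"ctg1"}
    Gk = geno.snp_density_filter(G, min_bp_per_snp=10.0)
    assert set(Gk.loci["contig"]) == {"ctg1", "ctg2"}


def test_ld_prune_audit():
    rng = np.random.default_rng(3)
    base = rng.binomial(2, 0.5, size=40).astype(float)
    dosage = np.column_stack([base, base.copy(), rng.binomial(2, 0.5, size=40)]).astype(float)
    loci = pd.DataFrame(
        {"contig": ["c"] * 3, "pos": [1, 2, 3], "ref": ["A"] * 3, "alt": ["G"] * 3,
         "locus_id": ["a", "b", "c"]}
    )
    samples = pd.DataFrame({"sample": [str(i) for i in range(40)], "provenance": "P"})
    G = GenotypeMatrix(dosage, loci, samples)
    Gp = geno.ld_prune(G, r2_max=0.5)
    kept = list(Gp.locus_ids())
    assert "a" in kept and "b" not in kept  # duplicate column pruned
    # audit: no surviving within-contig pair exceeds the threshold
    for i in range(Gp.n_loci):
        for j in range(i + 1, Gp.n_loci):
            r = np.corrcoef(Gp.dosage[:, i], Gp.dosage[:, j])[0, 1]
            assert r * r <= 0.5 + 1e-12


def test_ld_prune_cross_contig_not_compared():
    base = np.tile([0.0, 1.0, 2.0, 1.0], 5)
    dosage = np.column_stack([base, base])
    loci = pd.DataFrame(
        {"contig": ["c1", "c2"], "pos": [1, 1], "ref": ["A"] * 2, "alt": ["G"] * 2,
         "locus_id": ["a", "b"]}
    )
    samples = pd.DataFrame({"sample": [str(i) for i in range(20)], "provenance": "P"})
    Gp = geno.ld_prune(GenotypeMatrix(dosage, loci, samples), r2_max=0.5)
    assert Gp.n_loci == 2  # identical loci on different contigs both kept


def test_annotation_categories(toy_vcf, toy_gff3):
    G = geno.read_vcf(toy_vcf)
    ann = geno.annotate_snps(G, toy_gff3, flank=500)
    primary = ann.table.set_index("locus_id")["primary"]
    assert primary["v4"] == "CDS"            # 1200 in exon1 CDS
    assert primary["v5"] == "intron"         # 1500 between exons
    assert primary["v6"] == "three_prime_UTR"  # 2000 in exon2, 3'UTR
    assert primary["v3"] == "flank"          # 800, 200 bp left of gene
    assert primary["v1"] == "unclassified"   # 100, 900 bp away
    labels_v6 = ann.table.set_index("locus_id")["labels"]["v6"]
    assert {"exon", "three_prime_UTR"} <= set(labels_v6)
    # multi-label tally counts a CDS SNP as exon too
    t = ann.tally()
    assert t["exon"] >= t["CDS"]


def test_flank_boundary_500_501(tmp_path):
    vcf, gff, positions = make_flank_boundary_files(tmp_path)
    G = geno.read_vcf(vcf)
    ann = geno.annotate_snps(G, gff, flank=500)
    primary = ann.table.set_index("locus_id")["primary"]
    assert primary["left500"] == "flank"
    assert primary["right500"] == "flank"
    assert primary["left501"] == "unclassified"
    assert primary["right501"] == "unclassified"
    assert primary["inside"] == "CDS"


def test_expected_heterozygosity_oracle():
    G = _toy_matrix()
    he, mean_he = geno.expected_heterozygosity(G)
    for j in range(G.n_loci):
        col = G.dosage[:, j]
        p = np.nanmean(col) / 2.0
        assert he[j] == pytest.approx(1 - p**2 - (1 - p) ** 2, abs=1e-12)
    assert mean_he == pytest.approx(np.nanmean(he), abs=1e-12)


def test_individual_heterozygosity_oracle():
    G = _toy_matrix()
    het = geno.individual_heterozygosity(G)
    for i in range(G.n_individuals):
        row = G.dosage[i]
        called = np.sum(~np.isnan(row))
        assert het[i] == pytest.approx(np.nansum(row == 1) / called, abs=1e-12)


def test_impute_major_modal_and_ties():
    dosage = np.array(
        [[0.0, 2.0], [0.0, 2.0], [1.0, 0.0], [np.nan, np.nan], [1.0, 0.0]]
    )
    loci = pd.DataFrame(
        {"contig": ["c"] * 2, "pos": [1, 2], "ref": ["A"] * 2, "alt": ["G"] * 2,
         "locus_id": ["a", "b"]}
    )
    samples = pd.DataFrame({"sample": [str(i) for i in range(5)], "provenance": "P"})
    Gi = geno.impute_major(GenotypeMatrix(dosage, loci, samples))
    assert Gi.dosage[3, 0] == 0.0  # tie 0 vs 1 -> lower dosage
    assert Gi.dosage[3, 1] == 0.0  # 0 and 2 tie -> lower dosage


def test_allele_frequency_missing_aware():
    G = _toy_matrix()
    p = geno.allele_frequency(G)
    assert p[3] == pytest.approx(np.nanmean(G.dosage[:, 3]) / 2.0)
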