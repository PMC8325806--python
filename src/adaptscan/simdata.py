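"""Synthetic provenance-trial data with known truth.

Emulates a candidate-gene panel from a common-garden experiment: ~47
provenances on three correlated latent environmental gradients, ~92 weakly
admixed individuals from 3 genetic clusters, ~3000 biallelic SNPs grouped
into short gene contigs, a planted subset of loci whose allele frequencies
follow logistic clines on the latent factors, and provenance-level
phenotypes (spring/autumn phenology, height, survival) linked to the same
factors.

Neutral allele frequencies follow the Balding-Nichols model: cluster
frequencies are Beta-distributed around an ancestral frequency p0 with
spread set by FST.  Adaptive loci instead take frequency
inverse-logit(logit(p0) + slope * factor) at each individual's site, so the
planted truth is defined against the latent factor that the environmental
PCA recovers.  The ancestral frequency spectrum is Beta(0.7, 0.7) truncated
to [0.05, 0.95], which puts the expected sample heterozygosity near 0.29,
typical of candidate-gene SNP panels in outcrossing trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .geno import GenotypeMatrix, write_vcf, read_vcf


class InvalidConfigError(ValueError):
    pass


class InvalidGeneModelError(ValueError):
    pass


#: default SNP category proportions (the panel covers genes and their
#: <=500 bp flanks, so nothing is unclassified by default)
DEFAULT_CATEGORY_PROPS = {
    "CDS": 0.52,
    "five_prime_UTR": 0.08,
    "three_prime_UTR": 0.05,
    "intron": 0.23,
    "flank": 0.12,
    "unclassified": 0.0,
}

#: phenotype channel loadings on the three latent factors
DEFAULT_PHENO_LOADINGS = {
    "spring": (1.0, 0.0, 0.0),
    "autumn": (0.3, 0.0, 0.5),
    "height": (0.0, 0.6, 0.0),
}
#: survival loads on the height channel (trees that grow well survive) plus
#: a factor-3 contribution
DEFAULT_SURVIVAL = {"height_loading": 0.6, "factor_loadings": (0.0, 0.0, 0.4)}


@dataclass
class SimConfig:
    n_sites: int = 47
    n_ind: int = 92
    n_snps: int = 2909
    n_adaptive: int = 60
    n_env: int = 19
    n_clusters: int = 3
    fst: float = 0.05
    cline_slope: float = 1.0
    pheno_noise_sd: float = 1.0
    env_noise_sd: float = 0.3
    missing_rate: float = 0.0075
    admix_alpha: float = 2.0
    admix_sigma: float = 0.6
    cluster_factor: int = 2   # latent factor that patterns ancestry (lat-linked)
    driving_factor: int = 0   # latent factor that drives the planted clines
    snps_per_gene: int = 8
    category_props: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_PROPS))
    pheno_loadings: dict = field(default_factory=lambda: dict(DEFAULT_PHENO_LOADINGS))
    survival_params: dict = field(default_factory=lambda: dict(DEFAULT_SURVIVAL))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_ind, self.n_snps, self.n_env, self.n_clusters) <= 0:
            raise InvalidConfigError("dimensions must be positive")
        if self.n_adaptive > self.n_snps or self.n_adaptive < 0:
            raise InvalidConfigError("n_adaptive must be in [0, n_snps]")
        if self.n_ind < self.n_sites:
            raise InvalidConfigError("need at least one individual per site")
        if not (0.0 < self.fst < 1.0):
            raise InvalidConfigError("fst must be in (0, 1)")
        if self.pheno_noise_sd < 0:
            raise InvalidConfigError("pheno_noise_sd must be >= 0")


@dataclass
class SiteData:
    sites: pd.DataFrame     # provenance, longitude, latitude, altitude
    env: pd.DataFrame       # provenance x n_env bioclim-like variables
    factors: np.ndarray     # n_sites x 3 latent factors


@dataclass
class SimulatedDataset:
    config: SimConfig
    sites: SiteData
    genotypes: GenotypeMatrix
    truth: pd.DataFrame     # locus_id, is_adaptive, driving_factor, true_slope
    q_true: np.ndarray      # n_ind x n_clusters
    pheno: pd.DataFrame
    gene_models: pd.DataFrame  # GFF3-style feature table
    placement: pd.DataFrame    # locus_id -> planned category, gene


def _env_loading_matrix(n_env: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed-pattern loading matrix: each variable loads 0.95 on one factor
    (cyclically assigned, giving an 8/6/5 split for 19 variables)."""
    L = np.zeros((n_env, 3))
    # factor assignment: first ~42% to factor 1, ~32% to factor 2, rest factor 3
    cuts = [int(round(n_env * 0.42)), int(round(n_env * 0.74))]
    for j in range(n_env):
        f = 0 if j < cuts[0] else (1 if j < cuts[1] else 2)
        L[j, f] = 0.95
    return L


def simulate_sites(cfg: SimConfig, rng: np.random.Generator | None = None) -> SiteData:
    """Provenance sites on 3 latent environmental factors.

    Environmental variables are a noisy fixed-loading factor model, so the
    top-3 PCA of the standardized table recovers most of the variance.
    Longitude, latitude and altitude correlate negatively with factors
    1, 3 and 2 respectively (|r| ~ 0.8).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    F = rng.standard_normal((cfg.n_sites, 3))
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    L = _env_loading_matrix(cfg.n_env, rng)
    env = F @ L.T + cfg.env_noise_sd * rng.standard_normal((cfg.n_sites, cfg.n_env))
    prov = [f"P{i + 1:02d}" for i in range(cfg.n_sites)]
    env_df = pd.DataFrame(
        env, index=pd.Index(prov, name="provenance"),
        columns=[f"BIO{j + 1}" for j in range(cfg.n_env)],
    )

    def _geo(f, scale, offset):
        raw = -(0.8 * f + 0.6 * rng.standard_normal(cfg.n_sites))
        return offset + scale * raw

    sites = pd.DataFrame(
        {
            "longitude": _geo(F[:, 0], 7.0, 10.0),
            "latitude": _geo(F[:, 2], 3.0, 49.0),
            "altitude": _geo(F[:, 1], 250.0, 550.0),
        },
        index=env_df.index,
    )
    return SiteData(sites=sites, env=env_df, factors=F)


def _assign_individuals(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Site index per individual: every site gets one, the rest spread
    randomly with at most 4 individuals per site (provenance-trial style)."""
    site_of = list(range(cfg.n_sites))
    counts = np.ones(cfg.n_sites, dtype=int)
    for _ in range(cfg.n_ind - cfg.n_sites):
        open_sites = np.flatnonzero(counts < 4)
        if open_sites.size == 0:
            open_sites = np.arange(cfg.n_sites)
        s = int(rng.choice(open_sites))
        site_of.append(s)
        counts[s] += 1
    return np.array(sorted(site_of))


def _ancestral_frequencies(n: int, rng: np.random.Generator) -> np.ndarray:
    p0 = rng.beta(0.7, 0.7, size=n)
    return np.clip(p0, 0.05, 0.95)


def _dirichlet_q(cfg, factors, site_of, rng) -> np.ndarray:
    """Geographically patterned ancestry: Dirichlet concentration follows a
    Gaussian kernel on the distance, along the latitude-linked factor, to
    evenly spaced cluster centers.  Patterning ancestry on a different
    gradient than the selective one mirrors real ranges, where demographic
    history and the selective gradient are not the same axis."""
    coord = factors[:, cfg.cluster_factor]
    centers = np.quantile(coord, (np.arange(cfg.n_clusters) + 0.5) / cfg.n_clusters)
    q = np.empty((cfg.n_ind, cfg.n_clusters))
    for i, s in enumerate(site_of):
        w = np.exp(-((coord[s] - centers) ** 2) / (2 * cfg.admix_sigma**2))
        w = w / w.sum()
        alpha = cfg.admix_alpha * w + 0.02
        q[i] = rng.dirichlet(alpha)
    return q


def simulate_genotypes(
    cfg: SimConfig, sites: SiteData, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Admixed genotypes with planted logistic clines.

    Returns the genotype matrix, the truth table of planted loci and the
    true ancestry matrix Q.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    site_of = _assign_individuals(cfg, rng)
    q_true = _dirichlet_q(cfg, sites.factors, site_of, rng)

    p0 = _ancestral_frequencies(cfg.n_snps, rng)
    adaptive = np.zeros(cfg.n_snps, dtype=bool)
    if cfg.n_adaptive:
        adaptive[rng.choice(cfg.n_snps, size=cfg.n_adaptive, replace=False)] = True
        # keep planted loci at intermediate frequency so a cline is expressible
        p0[adaptive] = rng.uniform(0.3, 0.7, size=cfg.n_adaptive)

    # Balding-Nichols cluster frequencies for neutral loci
    a = p0 * (1 - cfg.fst) / cfg.fst
    b = (1 - p0) * (1 - cfg.fst) / cfg.fst
    f_clusters = rng.beta(
        np.broadcast_to(a, (cfg.n_clusters, cfg.n_snps)),
        np.broadcast_to(b, (cfg.n_clusters, cfg.n_snps)),
    )

    # individual-level allele frequencies
    p_ind = q_true @ f_clusters                       # n_ind x n_snps
    driving = sites.factors[site_of, cfg.driving_factor]
    if cfg.n_adaptive:
        cline = expit(
            logit(p0[adaptive])[None, :] + cfg.cline_slope * driving[:, None]
        )
        p_ind[:, adaptive] = cline

    # mixture of in-range frequencies can exceed [0, 1] by float round-off
    dosage = rng.binomial(2, np.clip(p_ind, 0.0, 1.0)).astype(float)
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = np.nan

    layout = _plan_layout(cfg, rng)
    loci = layout.copy()
    samples = pd.DataFrame(
        {
            "sample": [f"I{i + 1:03d}" for i in range(cfg.n_ind)],
            "provenance": sites.sites.index[site_of],
        }
    )
    G = GenotypeMatrix(
        dosage,
        loci,
        samples,
        contig_lengths=dict(
            layout.groupby("contig")["_contig_length"].first().astype(int)
        ),
    )
    truth = pd.DataFrame(
        {
            "locus_id": loci["locus_id"],
            "is_adaptive": adaptive,
            "driving_factor": np.where(adaptive, cfg.driving_factor, -1),
            "true_slope": np.where(adaptive, cfg.cline_slope, 0.0),
        }
    )
    return G, truth, q_true


# ---------------------------------------------------------------------------
# Gene-model layout
# ---------------------------------------------------------------------------

_CAT_ORDER = ["unclassified", "flank", "five_prime_UTR", "CDS", "intron",
              "three_prime_UTR"]


def _plan_layout(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign each SNP a contig, position and planned genomic category such
    that a one-gene-per-contig model can be constructed around it."""
    props = cfg.category_props
    total = sum(props.values())
    cats = list(props)
    probs = np.array([props[c] for c in cats]) / total
    planned = rng.choice(len(cats), size=cfg.n_snps, p=probs)
    planned_names = np.array(cats, dtype=object)[planned]

    n_genes = int(np.ceil(cfg.n_snps / cfg.snps_per_gene))
    gene_of = np.repeat(np.arange(n_genes), cfg.snps_per_gene)[: cfg.n_snps]

    rows = []
    for g in range(n_genes):
        idx = np.flatnonzero(gene_of == g)
        names = planned_names[idx]
        by_cat = {c: [int(i) for i in idx[names == c]] for c in cats}
        rows.extend(_layout_one_gene(g, by_cat))
    df = pd.DataFrame(rows).sort_values("_locus_index").reset_index(drop=True)
    df["locus_id"] = [f"snp{i + 1:05d}" for i in range(len(df))]
    df["ref"] = "A"
    df["alt"] = "G"
    return df[
        ["contig", "pos", "ref", "alt", "locus_id", "_category", "_gene",
         "_locus_index", "_gene_start", "_gene_end", "_cds_start", "_cds_end",
         "_exon_blocks", "_contig_length"]
    ]


def _layout_one_gene(g: int, by_cat: dict[str, list[int]]) -> list[dict]:
    """Construct one gene on its own contig and place SNPs.

    Geometry (1-based, left to right): unclassified SNPs (>500 bp left of
    the gene), left-flank SNPs (<=500 bp), gene start, 5'UTR SNPs in exon 1,
    CDS SNP chunks alternating with intron SNPs (each intron SNP in its own
    intron), 3'UTR SNPs at the end of the last exon, then right-flank and
    right unclassified SNPs.
    """
    contig = f"contig{g + 1:04d}"
    out = []
    step = 30
    uncls = by_cat.get("unclassified", [])
    flanks = by_cat.get("flank", [])
    u_left, u_right = uncls[: len(uncls) // 2], uncls[len(uncls) // 2:]
    f_left, f_right = flanks[: len(flanks) // 2], flanks[len(flanks) // 2:]

    cursor = 100
    for i in u_left:
        out.append({"_locus_index": i, "_category": "unclassified", "pos": cursor})
        cursor += step
    gene_start = (out[-1]["pos"] if u_left else cursor) + 600
    pos = gene_start - 500 + 10
    for i in f_left:
        out.append({"_locus_index": i, "_category": "flank", "pos": pos})
        pos += step

    # inside the gene
    pos = gene_start + 10
    exon_blocks: list[list[int]] = [[gene_start, None]]
    for i in by_cat.get("five_prime_UTR", []):
        out.append({"_locus_index": i, "_category": "five_prime_UTR", "pos": pos})
        pos += step
    cds_start = pos
    pos += 10
    cds_snps = by_cat.get("CDS", [])
    introns = by_cat.get("intron", [])
    n_chunks = len(introns) + 1
    chunks = np.array_split(np.array(cds_snps, dtype=int), n_chunks)
    for c, chunk in enumerate(chunks):
        for i in chunk:
            out.append({"_locus_index": int(i), "_category": "CDS", "pos": pos})
            pos += step
        if c < len(introns):
            exon_blocks[-1][1] = pos            # close exon just past last SNP
            pos += 20
            out.append({"_locus_index": introns[c], "_category": "intron", "pos": pos})
            pos += 20
            exon_blocks.append([pos, None])     # open next exon
            pos += 10
    cds_end = pos
    pos += 10
    for i in by_cat.get("three_prime_UTR", []):
        out.append({"_locus_index": i, "_category": "three_prime_UTR", "pos": pos})
        pos += step
    gene_end = pos + 10
    exon_blocks[-1][1] = gene_end

    pos = gene_end + 100
    for i in f_right:
        out.append({"_locus_index": i, "_category": "flank", "pos": pos})
        pos += step
    pos = gene_end + 600
    for i in u_right:
        out.append({"_locus_index": i, "_category": "unclassified", "pos": pos})
        pos += step
    contig_length = pos + 600

    for rec in out:
        rec.update(
            contig=contig,
            _gene=f"gene{g + 1:04d}",
            _gene_start=gene_start,
            _gene_end=gene_end,
            _cds_start=cds_start,
            _cds_end=cds_end,
            _exon_blocks=json.dumps([[int(s), int(e)] for s, e in exon_blocks]),
            _contig_length=contig_length,
        )
    return out


def simulate_gene_models(cfg: SimConfig, loci: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-model feature table (GFF3 columns) and SNP placement truth.

    Features are reconstructed from the layout plan carried in the locus
    metadata; overlapping exon blocks raise an invalid-model error.
    """
    if "_gene" not in loci.columns:
        raise ValueError("loci table lacks layout plan; generate via simulate_genotypes")
    feats = []
    for gene, sub in loci[loci["_gene"].notna()].groupby("_gene", sort=True):
        row = sub.iloc[0]
        contig = row["contig"]
        gs, ge = int(row["_gene_start"]), int(row["_gene_end"])
        cs, ce = int(row["_cds_start"]), int(row["_cds_end"])
        exons = json.loads(row["_exon_blocks"])
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise InvalidGeneModelError(f"overlapping exons in {gene}")
        feats.append((contig, "gene", gs, ge, gene, None))
        for k, (s, e) in enumerate(exons):
            feats.append((contig, "exon", s, e, f"{gene}.exon{k + 1}", gene))
            cds_s, cds_e = max(s, cs), min(e, ce)
            if cds_s <= cds_e:
                feats.append((contig, "CDS", cds_s, cds_e, f"{gene}.cds{k + 1}", gene))
        first_s, first_e = exons[0]
        if first_s <= cs - 1:
            feats.append((contig, "five_prime_UTR", first_s, cs - 1, f"{gene}.utr5", gene))
        last_s, last_e = exons[-1]
        if ce + 1 <= last_e:
            feats.append((contig, "three_prime_UTR", ce + 1, last_e, f"{gene}.utr3", gene))
    gene_models = pd.DataFrame(
        feats, columns=["contig", "type", "start", "end", "feature_id", "parent"]
    )
    placement = loci[["locus_id", "_category", "_gene"]].rename(
        columns={"_category": "category", "_gene": "gene"}
    )
    placement = placement.copy()
    placement.loc[placement["category"] == "unclassified", "gene"] = None
    return gene_models, placement


def write_gff3(gene_models: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in gene_models.iterrows():
            attrs = f"ID={r['feature_id']}"
            if r["parent"]:
                attrs += f";Parent={r['parent']}"
            fh.write(
                f"{r['contig']}\tsim\t{r['type']}\t{int(r['start'])}\t"
                f"{int(r['end'])}\t.\t+\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    cfg: SimConfig, sites: SiteData, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Provenance-level phenotypes linked to the latent factors.

    Spring phenology is linear in the driving factor (factor 1); survival
    loads positively on the height channel.  Outputs are rescaled to
    plausible units (7-point score, cm, percent) but not clipped, so
    noiseless correlations are exact.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    F = sites.factors
    n = cfg.n_sites
    z = {}
    for name, lo in cfg.pheno_loadings.items():
        z[name] = F @ np.asarray(lo) + cfg.pheno_noise_sd * rng.standard_normal(n)
    sp = cfg.survival_params
    z["survival"] = (
        sp["height_loading"] * z["height"]
        + F @ np.asarray(sp["factor_loadings"])
        + cfg.pheno_noise_sd * rng.standard_normal(n)
    )
    pheno = pd.DataFrame(
        {
            "spring": 4.0 + 1.2 * z["spring"],
            "autumn": 3.0 + 1.0 * z["autumn"],
            "height": 150.0 + 25.0 * z["height"],
            "survival": 70.0 + 10.0 * z["survival"],
        },
        index=sites.sites.index,
    )
    pheno["L"] = pheno["spring"] - pheno["autumn"]
    return pheno


# ---------------------------------------------------------------------------
# Top-level generation and file round-trip
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig) -> SimulatedDataset:
    """Generate a full dataset deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    sites = simulate_sites(cfg, rng)
    G, truth, q_true = simulate_genotypes(cfg, sites, rng)
    pheno = simulate_phenotypes(cfg, sites, rng)
    gene_models, placement = simulate_gene_models(cfg, G.loci)
    return SimulatedDataset(
        config=cfg,
        sites=sites,
        genotypes=G,
        truth=truth,
        q_true=q_true,
        pheno=pheno,
        gene_models=gene_models,
        placement=placement,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write VCF + TSV + GFF3 files; everything round-trips losslessly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "gff3": outdir / "gene_models.gff3",
        "sites": outdir / "sites.tsv",
        "env": outdir / "environment.tsv",
        "pheno": outdir / "phenotypes.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_vcf(ds.genotypes, paths["vcf"])
    write_gff3(ds.gene_models, paths["gff3"])
    ds.sites.sites.to_csv(paths["sites"], sep="\t")
    ds.sites.env.to_csv(paths["env"], sep="\t")
    ds.pheno.to_csv(paths["pheno"], sep="\t")
    ds.genotypes.samples.to_csv(paths["samples"], sep="\t", index=False)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = asdict(ds.config)
    with open(paths["manifest"], "w") as fh:
        json.dump({"seed": ds.config.seed, "config": cfg}, fh, indent=2, default=str)
    return paths


def read_dataset(outdir):
    """Load a written dataset back (genotypes, tables)."""
    outdir = Path(outdir)
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
    prov = dict(zip(samples["sample"], samples["provenance"]))
    G = read_vcf(outdir / "genotypes.vcf", provenances=prov)
    sites = pd.read_csv(outdir / "sites.tsv", sep="\t", index_col=0)
    env = pd.read_csv(outdir / "environment.tsv", sep="\t", index_col=0)
    pheno = pd.read_csv(outdir / "phenotypes.tsv", sep="\t", index_col=0)
    return G, sites, env, pheno
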