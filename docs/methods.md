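# Methods

This document records the statistical models, the default parameter choices
and their rationale, and known limitations.

## Simulator (`simdata`)

The generator mimics a common-garden provenance trial: trees sampled from
sites along a geographic/climatic gradient, genotyped at SNPs inside
candidate genes, and phenotyped for phenology and growth.

- **Sites.** Each of `n_sites` (default 47) sites carries `n_env` (19)
  correlated environmental variables generated from three latent factors plus
  noise (`env_noise_sd` 0.3). Longitude, latitude and altitude are affine in
  a latitude-linked factor, with negative sign so that "northern" sites have
  low factor values.
- **Structure.** Individuals (92) have Dirichlet admixture proportions Q
  over `n_clusters` (3) ancestral clusters; the Dirichlet mean shifts with
  the latitude-linked factor (`cluster_factor` 2) so structure is spatially
  confounded, as in real data. Cluster allele frequencies follow a
  Balding–Nichols model around an ancestral frequency `p0 ~ Beta(0.7, 0.7)`
  clipped to [0.05, 0.95], with divergence `fst` (default 0.05). The Beta
  shape was chosen so that the mean expected heterozygosity of polymorphic,
  filter-passing loci lands near 0.29–0.34, typical of candidate-gene SNP
  panels.
- **Adaptive loci.** `n_adaptive` (60) loci get logistic clines
  `p = expit(logit(p0) + slope · f)` on a *different* latent factor
  (`driving_factor` 0) than the one patterning structure, so signal and
  structure are correlated only through the factor covariance — a harder and
  more realistic test than independence.
- **Phenotypes.** Spring/autumn phenology and height are linear in the
  latent factors plus noise; survival adds a height loading. A derived
  "growing season" L column is appended.
- **Gene models.** SNPs are placed inside synthetic genes
  (`snps_per_gene` 8) with exons, CDS and UTRs, written as GFF3, so the
  annotation code paths are exercised end to end. Datasets round-trip through
  VCF + GFF3 + TSV + a JSON manifest.

Limitations: no linkage beyond the deliberate within-gene placement, no
selfing/relatedness, site-level environment only (no microsite variation),
and clines act on single loci rather than a quantitative-trait architecture.

## Filtering and annotation (`geno`)

Genotype calls below `min_depth` (10) are set missing; loci are dropped at
MAF < 0.05 or missingness > 0.25; contigs denser than one SNP per 10 bp are
thinned; LD pruning removes one locus of each within-contig pair with
r² > 0.5 (earlier position kept). Annotation labels each SNP with all
overlapping feature classes and a primary label by priority CDS >
5′UTR > 3′UTR > exon > intron > flank > unclassified, with the flank
extending exactly `flank` (500) bp beyond the gene span: a SNP 500 bp away is
flank, 501 bp away is unclassified.

## Ancestry (`ancestry`)

A likelihood-based admixture model (multiplicative updates on Q and cluster
frequencies F, simplex-projected, multi-restart) is scored by holdout
cross-entropy on 5 % of entries. `select_k` picks the smallest K within one
standard error of the best mean score across replicates; a ΔK (second
difference of replicate means over replicate SD) table is also available.
`impute_ancestry` fills missing genotypes with `2 · qᵢ · F` expectations,
which beats major-genotype imputation whenever structure is appreciable.

## Latent-factor scans (`lfmm`)

Latent factors are the top singular vectors (scaled by singular values) of
the centered dosage matrix. Each environmental/phenotypic variable is scanned
by per-locus OLS of dosage on the variable plus the factors; z-scores are
genomic-control calibrated (λ = median z² / 0.4549) and the candidate rule is
conjunctive: BH q ≤ 0.01 **and** calibrated p < 0.001.

**Number of factors.** With K ancestry clusters the rows of Q live on a
simplex, so the column-centered structure signal spans K−1 dimensions. The
pipeline therefore uses K−1 latent factors. Using K factors makes the K-th
singular vector lock onto whatever coherent non-structure signal is
strongest — with many planted clines that is the cline direction itself, and
the scan's power collapses while calibration still looks perfect. This is an
identity of the model, not a tuning choice, and it is covered by tests.

## Redundancy analysis (`rda`)

RDA fits the multi-locus regression of centered dosages on the predictor
table (geography, climate PCs, phenotypes after a collinearity prescreen at
|r| > 0.7, keeping the higher-priority variable) and extracts constrained
axes by PCA of the fitted values. Significance uses permutation pseudo-F
tests, global and sequentially per axis. Outliers are loci whose loadings on
a significant axis (at most the first two) exceed 3 SD; each outlier is
assigned the predictor it correlates with most strongly. Regional (within
ancestry cluster) reruns catch clines whose sign flips between clusters and
would cancel globally.

**Known false-discovery behavior.** When population structure is correlated
with the predictors — which is exactly the provenance-trial situation — the
first constrained axis is largely the structure axis, and its 3 SD loading
tail contains high-drift neutral loci. In simulation these are false
positives relative to planted truth: across ten generator seeds at a cline
strength giving mean |r| ≈ 0.4, the LFMM ∪ RDA union recovers ~76 % of
planted loci but with an empirical union FDR of ~23 %, above a 20 % bound,
with essentially the whole excess contributed by RDA structure-axis outliers
(LFMM alone contributes 1–4 false positives per seed). Simple RDA (as opposed
to partial RDA conditioned on ancestry) is the intended protocol here, so
the behavior is documented, asserted in the acceptance test, and left
visible rather than patched around. Treat RDA-only candidates on axis 1
with caution; the intersection set is much cleaner than the union.

## Variance partition (`partition`)

Four models on the candidate dosage matrix: full RDA on geography + climate +
phenotype, plus each block conditioned on the other two (partial RDA).
Percentages are relative to the full model's constrained inertia and the
unique + joint fractions sum to 100 % exactly (audited to 1e−8). With
mutually orthogonal blocks the joint fraction is zero and each unique inertia
equals the single-block RDA inertia.

## Polygenic scores (`polyscore`)

For each variable, candidate alleles are polarized to the allele whose
frequency increases with the variable; the score counts favored alleles
(missing genotypes contribute the locus mean). Linear and quadratic trends
are compared by AIC. A backward-elimination OLS relates individual
heterozygosity to the environment.

## Pipeline defaults (`pipeline.RunConfig`)

depth ≥ 10, MAF ≥ 0.05, missingness ≤ 0.25, ≥ 10 bp per SNP, LD r² ≤ 0.5,
prescreen |r| ≤ 0.7, outlier threshold 3 SD on at most 2 significant axes,
FDR 0.01 with p < 0.001, 1000 global / 999 partition permutations, K searched
over 1–10 with 3 replicates, 3 climate PCs, 500 bp annotation flank, 150 bp
LFMM–RDA proximity window. All stages draw stage-specific seeds from one
run seed, so runs are exactly reproducible.
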