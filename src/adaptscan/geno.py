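"""Genotype containers, VCF I/O, variant filtering, LD pruning, SNP
annotation against gene models, diversity statistics and naive imputation.

Dosages count copies of the ALT allele (0/1/2); missing genotypes are
``numpy.nan``.  All correlation-based downstream steps are invariant to a
global REF/ALT recoding, so the coding is purely presentational.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical ordering used when one primary label per locus is required
ANNOTATION_PRIORITY = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "exon",
    "intron",
    "flank",
    "unclassified",
)


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci ALT-allele dosage matrix with locus metadata.

    Attributes
    ----------
    dosage : (n_ind, n_loci) float array with entries in {0, 1, 2, nan}.
    loci : DataFrame with columns ``contig``, ``pos`` (1-based), ``ref``,
        ``alt`` and optional extras; one row per locus, aligned to columns
        of ``dosage``.
    samples : DataFrame with columns ``sample`` and ``provenance``.
    depth : optional per-genotype read depth, same shape as ``dosage``.
    contig_lengths : optional mapping contig -> length in bp (from VCF
        header), used by the SNP-density filter.
    """

    dosage: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame
    depth: np.ndarray | None = None
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x loci)")
        if self.dosage.shape[1] != len(self.loci):
            raise ValueError("loci metadata does not match dosage columns")
        if self.dosage.shape[0] != len(self.samples):
            raise ValueError("sample table does not match dosage rows")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def locus_ids(self) -> pd.Index:
        if "locus_id" in self.loci.columns:
            return pd.Index(self.loci["locus_id"])
        return pd.Index(
            self.loci["contig"].astype(str) + ":" + self.loci["pos"].astype(str)
        )

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            dosage=self.dosage[:, idx],
            loci=self.loci.iloc[idx].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            dosage=self.dosage[idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosage=self.dosage.copy(),
            loci=self.loci.copy(),
            samples=self.samples.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            contig_lengths=dict(self.contig_lengths),
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path, provenances: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (counts logged).  ``./.``
    genotypes become ``nan``.  Per-genotype depth is kept when a DP FORMAT
    field is present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[dict] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    has_depth = False
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        dosage_cols.append(dos)
        rows.append(
            {
                "contig": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "locus_id": rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}",
            }
        )
        try:
            dp = rec.format("DP")
        except Exception:
            dp = None
        if dp is not None:
            has_depth = True
            depth_cols.append(dp[:, 0].astype(float))
        else:
            depth_cols.append(np.full(len(samples), np.nan))
    contig_lengths = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            inner = line.split("<", 1)[1].rstrip(">")
            kv = dict(part.split("=", 1) for part in inner.split(","))
            if "ID" in kv and "length" in kv:
                contig_lengths[kv["ID"]] = int(kv["length"])
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        warnings.warn("VCF contained no usable biallelic SNP records")
        dosage = np.empty((len(samples), 0))
        depth = None
    else:
        dosage = np.column_stack(dosage_cols)
        depth = np.column_stack(depth_cols) if has_depth else None
    loci = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "locus_id"])
    sample_df = pd.DataFrame({"sample": samples})
    sample_df["provenance"] = (
        sample_df["sample"].map(provenances) if provenances else pd.NA
    )
    return GenotypeMatrix(dosage, loci, sample_df, depth=depth, contig_lengths=contig_lengths)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF v4.2 with GT (and DP) fields."""
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in pd.unique(G.loci["contig"]):
            length = G.contig_lengths.get(contig)
            if length is None:
                length = int(G.loci.loc[G.loci["contig"] == contig, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fmt = "GT"
        if G.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fmt = "GT:DP"
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples["sample"].astype(str))
            + "\n"
        )
        ids = G.locus_ids()
        for j in range(G.n_loci):
            row = G.loci.iloc[j]
            cells = []
            for i in range(G.n_individuals):
                d = G.dosage[i, j]
                gt = "./." if np.isnan(d) else gt_codes[float(d)]
                if G.depth is not None:
                    dp = G.depth[i, j]
                    gt = f"{gt}:{int(dp) if np.isfinite(dp) else '.'}"
                cells.append(gt)
            fh.write(
                f"{row['contig']}\t{int(row['pos'])}\t{ids[j]}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    """ALT allele frequency per locus over non-missing genotypes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(G.dosage, axis=0) / 2.0


def filter_variants(
    G: GenotypeMatrix,
    min_depth: int = 10,
    maf: float = 0.05,
    max_missing: float = 0.25,
    log: list | None = None,
) -> GenotypeMatrix:
    """Depth-mask genotypes and drop loci failing MAF / missingness cut-offs.

    Genotypes with read depth below ``min_depth`` are set missing (when depth
    information is available).  Loci are then dropped if the minor allele
    frequency is <= ``maf`` or the missing fraction is >= ``max_missing``.
    """
    G = G.copy()
    if G.depth is not None:
        low = np.isfinite(G.depth) & (G.depth < min_depth)
        G.dosage[low] = np.nan
    n0 = G.n_loci
    p = allele_frequency(G)
    minor = np.minimum(p, 1 - p)
    keep_maf = minor > maf
    miss_frac = np.mean(np.isnan(G.dosage), axis=0)
    keep_miss = miss_frac < max_missing
    keep = keep_maf & keep_miss & np.isfinite(p)
    if log is not None:
        log.append(("maf", n0, int(np.sum(keep_maf))))
        log.append(("missingness", n0, int(np.sum(keep_miss))))
        log.append(("combined", n0, int(np.sum(keep))))
    return G.subset_loci(keep)


def snp_density_filter(
    G: GenotypeMatrix, min_bp_per_snp: float = 10.0
) -> GenotypeMatrix:
    """Drop whole contigs whose bp-per-SNP density is below the threshold.

    Density uses contig length from the VCF header; contigs without a known
    length are kept with a warning.
    """
    counts = G.loci["contig"].value_counts()
    drop: set[str] = set()
    for contig, n in counts.items():
        length = G.contig_lengths.get(contig)
        if length is None:
            warnings.warn(f"no length for contig {contig!r}; kept unfiltered")
            continue
        if length / n < min_bp_per_snp:
            drop.add(contig)
    keep = ~G.loci["contig"].isin(drop).to_numpy()
    return G.subset_loci(keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(G: GenotypeMatrix, r2_max: float = 0.5) -> GenotypeMatrix:
    """Greedy within-contig LD pruning.

    Loci are scanned left to right within each contig; a locus is kept iff
    its squared Pearson correlation (pairwise-complete dosages) with every
    previously kept locus on the same contig is <= ``r2_max``.  Loci on
    different contigs are never compared.
    """
    keep = np.ones(G.n_loci, dtype=bool)
    contigs = G.loci["contig"].to_numpy()
    order = np.lexsort((G.loci["pos"].to_numpy(), contigs))
    by_contig: dict[str, list[int]] = {}
    for j in order:
        kept = by_contig.setdefault(contigs[j], [])
        col = G.dosage[:, j]
        if any(_pairwise_r2(col, G.dosage[:, k]) > r2_max for k in kept):
            keep[j] = False
        else:
            kept.append(j)
    return G.subset_loci(keep)


# ---------------------------------------------------------------------------
# Gene-model annotation
# ---------------------------------------------------------------------------

@dataclass
class SnpAnnotation:
    """Per-locus genomic-region labels against gene models.

    ``table`` has one row per locus with columns ``locus_id``, ``contig``,
    ``pos``, ``gene`` (or None), ``labels`` (frozenset of all applicable
    labels) and ``primary`` (single highest-priority label).
    """

    table: pd.DataFrame

    def tally(self) -> pd.Series:
        """Multi-label counts per category (a CDS SNP counts as exon too)."""
        counts = {lab: 0 for lab in ANNOTATION_PRIORITY}
        for labels in self.table["labels"]:
            for lab in labels:
                counts[lab] += 1
        return pd.Series(counts)

    def primary_tally(self) -> pd.Series:
        return self.table["primary"].value_counts().reindex(
            ANNOTATION_PRIORITY, fill_value=0
        )

    def gene_of(self) -> pd.Series:
        return self.table.set_index("locus_id")["gene"]


def _load_gene_features(gff3_path):
    """Parse gene/exon/CDS/UTR features per contig from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for gene in db.features_of_type("gene"):
        feats = {"exon": [], "CDS": [], "five_prime_UTR": [], "three_prime_UTR": []}
        for child in db.children(gene, featuretype=tuple(feats)):
            feats[child.featuretype].append((child.start, child.end))
        genes.append(
            {
                "gene_id": gene.id,
                "contig": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "features": feats,
            }
        )
    return genes


def annotate_snps(G: GenotypeMatrix, gene_models, flank: int = 500) -> SnpAnnotation:
    """Classify each SNP relative to gene models (GFF3, 1-based inclusive).

    Categories by containment: CDS and UTRs lie within exons; intron = in
    gene but in no exon; flank = within ``flank`` bp outside the gene span
    (inclusive); unclassified otherwise.  The full label set is retained
    (a CDS SNP is also an exon SNP); ``primary`` applies the priority
    CDS > 5'UTR > 3'UTR > exon > intron > flank.
    """
    genes = _load_gene_features(gene_models)
    by_contig: dict[str, list[dict]] = {}
    for g in genes:
        by_contig.setdefault(g["contig"], []).append(g)

    def _in(pos, intervals):
        return any(s <= pos <= e for s, e in intervals)

    records = []
    ids = G.locus_ids()
    for j in range(G.n_loci):
        contig = G.loci["contig"].iloc[j]
        pos = int(G.loci["pos"].iloc[j])
        labels: set[str] = set()
        gene_id = None
        for g in by_contig.get(contig, []):
            if g["start"] <= pos <= g["end"]:
                gene_id = g["gene_id"]
                f = g["features"]
                if _in(pos, f["exon"]):
                    labels.add("exon")
                    if _in(pos, f["CDS"]):
                        labels.add("CDS")
                    if _in(pos, f["five_prime_UTR"]):
                        labels.add("five_prime_UTR")
                    if _in(pos, f["three_prime_UTR"]):
                        labels.add("three_prime_UTR")
                else:
                    labels.add("intron")
                break
            if g["start"] - flank <= pos <= g["end"] + flank:
                gene_id = g["gene_id"]
                labels.add("flank")
                break
        if not labels:
            labels.add("unclassified")
        primary = next(lab for lab in ANNOTATION_PRIORITY if lab in labels)
        records.append(
            {
                "locus_id": ids[j],
                "contig": contig,
                "pos": pos,
                "gene": gene_id,
                "labels": frozenset(labels),
                "primary": primary,
            }
        )
    return SnpAnnotation(pd.DataFrame(records))


# ---------------------------------------------------------------------------
# Diversity statistics and imputation
# ---------------------------------------------------------------------------

def expected_heterozygosity(G: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Per-locus expected heterozygosity He = 1 - p^2 - (1-p)^2 and its mean.

    ``p`` is the ALT allele frequency over non-missing alleles.  Loci with
    no called genotypes are excluded from the mean (warned).
    """
    p = allele_frequency(G)
    he = 1.0 - p**2 - (1.0 - p) ** 2
    if np.any(~np.isfinite(he)):
        warnings.warn("loci with no called genotypes excluded from mean He")
    return he, float(np.nanmean(he))


def individual_heterozygosity(
    G: GenotypeMatrix, loci_subset: np.ndarray | None = None
) -> np.ndarray:
    """Per-individual fraction of heterozygous calls within a locus subset."""
    d = G.dosage if loci_subset is None else G.dosage[:, np.asarray(loci_subset)]
    if d.shape[1] == 0:
        raise ValueError("locus subset is empty")
    called = np.sum(~np.isnan(d), axis=1).astype(float)
    het = np.nansum(d == 1, axis=1)
    out = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    if np.any(called == 0):
        warnings.warn("individuals with no called genotypes in subset -> nan")
    return out


def impute_major(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing entries by the modal genotype of each locus.

    Ties between genotype classes break toward the lower dosage.  A locus
    with no observed genotypes is an error (it should have been filtered).
    """
    G = G.copy()
    d = G.dosage
    for j in range(G.n_loci):
        col = d[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"locus {j} fully missing; filter before imputing")
        counts = np.array([(obs == k).sum() for k in (0, 1, 2)])
        col[miss] = float(np.argmax(counts))  # argmax ties -> lower dosage
    return G
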