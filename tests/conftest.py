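"""Shared fixtures: a small simulated dataset and toy VCF/GFF3 files."""

import numpy as np
import pandas as pd
import pytest

from adaptscan.simdata import SimConfig, simulate


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_sites=12, n_ind=30, n_snps=300, n_adaptive=10,
        cline_slope=1.5, seed=7,
    )


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return simulate(small_cfg)


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=ctg1,length=5000>
##contig=<ID=ctg2,length=40>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
ctg1\t100\tv1\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:50\t0/1:50\t1/1:50\t0/1:50
ctg1\t130\tv2\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:50\t0/1:50\t1/1:50\t0/1:50
ctg1\t800\tv3\tC\tT\t.\tPASS\t.\tGT:DP\t0/0:50\t0/0:50\t0/0:50\t0/1:5
ctg1\t1200\tv4\tC\tT\t.\tPASS\t.\tGT:DP\t./.:50\t./.:50\t0/1:50\t0/1:50
ctg1\t1500\tv5\tG\tA\t.\tPASS\t.\tGT:DP\t0/1:50\t0/0:50\t1/1:50\t0/0:50
ctg1\t2000\tv6\tG\tA\t.\tPASS\t.\tGT:DP\t0/0:50\t0/0:50\t0/0:50\t0/0:50
ctg2\t10\tv7\tT\tC\t.\tPASS\t.\tGT:DP\t0/1:50\t0/1:50\t0/0:50\t1/1:50
ctg2\t20\tv8\tT\tC\t.\tPASS\t.\tGT:DP\t0/1:50\t0/0:50\t0/1:50\t1/1:50
"""

# one gene on ctg1: gene 1000-2000, exon1 1000-1400, exon2 1600-2000,
# CDS 1100-1800 (split over the exons), 5'UTR 1000-1099, 3'UTR 1801-2000.
TOY_GFF3 = """\
##gff-version 3
ctg1\ttoy\tgene\t1000\t2000\t.\t+\t.\tID=geneA
ctg1\ttoy\texon\t1000\t1400\t.\t+\t.\tID=geneA.e1;Parent=geneA
ctg1\ttoy\texon\t1600\t2000\t.\t+\t.\tID=geneA.e2;Parent=geneA
ctg1\ttoy\tCDS\t1100\t1400\t.\t+\t.\tID=geneA.c1;Parent=geneA
ctg1\ttoy\tCDS\t1600\t1800\t.\t+\t.\tID=geneA.c2;Parent=geneA
ctg1\ttoy\tfive_prime_UTR\t1000\t1099\t.\t+\t.\tID=geneA.u5;Parent=geneA
ctg1\ttoy\tthree_prime_UTR\t1801\t2000\t.\t+\t.\tID=geneA.u3;Parent=geneA
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture()
def toy_gff3(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF3)
    return p


def make_flank_boundary_files(tmp_path):
    """VCF + GFF3 with SNPs exactly 500 and 501 bp outside a gene."""
    gene_start, gene_end = 2000, 3000
    positions = {
        "left501": gene_start - 501,   # unclassified
        "left500": gene_start - 500,   # flank
        "inside": 2500,                # in gene
        "right500": gene_end + 500,    # flank
        "right501": gene_end + 501,    # unclassified
    }
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=ctgF,length=10000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2",
    ]
    for name, pos in positions.items():
        lines.append(f"ctgF\t{pos}\t{name}\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1")
    vcf = tmp_path / "flank.vcf"
    vcf.write_text("\n".join(lines) + "\n")
    gff = tmp_path / "flank.gff3"
    gff.write_text(
        "##gff-version 3\n"
        f"ctgF\ttoy\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\tID=geneF\n"
        f"ctgF\ttoy\texon\t{gene_start}\t{gene_end}\t.\t+\t.\tID=geneF.e1;Parent=geneF\n"
        f"ctgF\ttoy\tCDS\t{gene_start}\t{gene_end}\t.\t+\t.\tID=geneF.c1;Parent=geneF\n"
    )
    return vcf, gff, positions
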