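"""Allele-specific expression (ASE) fractions and primary/secondary alleles.

The statistic is the *folded* secondary-allele fraction of a heterozygous
SNP: ``min(a, b) / (a + b)``, the fraction of transcript reads mapping to
the less expressed allele.  It lies in [0, 0.5]; 0 means strictly
monoallelic expression (intact silencing of the inactive X copy), 0.5 means
perfectly biallelic expression (full erosion or an escapee gene).

SNPs with fewer than ``min_reads_per_snp`` overlapping reads (default 20)
are excluded, silently — a shallow SNP is "not measurable", not an error.
Gene-level values are unweighted means of per-SNP fractions; band- and
chromosome-level values pool all passing SNPs in the region (not means of
gene means), with a gene-mean alternative available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AseConfig:
    min_reads_per_snp: int = 20

    def __post_init__(self):
        if self.min_reads_per_snp < 1:
            raise ValueError("min_reads_per_snp must be >= 1")


def snp_secondary_fraction(allele_a_count: int, allele_b_count: int) -> float:
    """Folded fraction of reads on the less expressed allele of one SNP."""
    total = allele_a_count + allele_b_count
    if total <= 0:
        raise ValueError("SNP with zero total reads has no allele fraction")
    return min(allele_a_count, allele_b_count) / total


def passing_snp_fractions(allele_counts: pd.DataFrame, config: AseConfig | None = None) -> pd.DataFrame:
    """Per-SNP folded fractions for SNPs meeting the read-depth threshold.

    Returns the passing subset of ``allele_counts`` with a
    ``secondary_fraction`` column appended.
    """
    config = config or AseConfig()
    a = allele_counts["allele_a_count"].to_numpy(dtype=float)
    b = allele_counts["allele_b_count"].to_numpy(dtype=float)
    total = a + b
    keep = total >= config.min_reads_per_snp
    out = allele_counts.loc[keep].copy()
    out["secondary_fraction"] = np.minimum(a[keep], b[keep]) / total[keep]
    return out


def gene_ase_fractions(allele_counts: pd.DataFrame, config: AseConfig | None = None) -> pd.DataFrame:
    """Per-(line, gene) ASE: unweighted mean of passing per-SNP fractions.

    Genes without a passing SNP in a line are absent from the output — the
    quantity is undefined there, not zero.
    """
    snps = passing_snp_fractions(allele_counts, config)
    if not len(snps):
        return pd.DataFrame(columns=["line_id", "gene_id", "secondary_fraction", "n_snps_used"])
    grouped = snps.groupby(["line_id", "gene_id"], sort=True)["secondary_fraction"]
    out = grouped.agg(secondary_fraction="mean", n_snps_used="size").reset_index()
    out["n_snps_used"] = out["n_snps_used"].astype(int)
    return out


def aggregate_ase(
    allele_counts: pd.DataFrame,
    annotation: pd.DataFrame,
    level: str = "chromosome",
    config: AseConfig | None = None,
    method: str = "pooled",
) -> pd.DataFrame:
    """Per-(line, band-or-chromosome) ASE fractions.

    ``method="pooled"`` (default) averages over all passing SNPs in the
    region; ``method="gene_mean"`` averages the per-gene fractions instead.
    Regions with no passing SNP are omitted.
    """
    if level not in ("band", "chromosome"):
        raise ValueError(f"level must be 'band' or 'chromosome', got {level!r}")
    if method not in ("pooled", "gene_mean"):
        raise ValueError(f"method must be 'pooled' or 'gene_mean', got {method!r}")
    region = annotation.set_index("gene_id")["cytoband" if level == "band" else "chromosome"]

    if method == "pooled":
        snps = passing_snp_fractions(allele_counts, config).copy()
        snps["key"] = snps["gene_id"].map(region)
        snps = snps.dropna(subset=["key"])
        grouped = snps.groupby(["line_id", "key"], sort=True)["secondary_fraction"]
        out = grouped.agg(secondary_fraction="mean", n_snps_used="size").reset_index()
    else:
        genes = gene_ase_fractions(allele_counts, config).copy()
        genes["key"] = genes["gene_id"].map(region)
        genes = genes.dropna(subset=["key"])
        grouped = genes.groupby(["line_id", "key"], sort=True)
        out = grouped.agg(
            secondary_fraction=("secondary_fraction", "mean"),
            n_snps_used=("n_snps_used", "sum"),
        ).reset_index()
    out["level"] = level
    out["n_snps_used"] = out["n_snps_used"].astype(int)
    return out[["level", "line_id", "key", "secondary_fraction", "n_snps_used"]]


def assign_primary_allele(allele_counts: pd.DataFrame, config: AseConfig | None = None) -> pd.DataFrame:
    """Per-(line, gene) primary allele: the larger summed count over passing SNPs.

    Ties go to allele_a (a documented, deterministic tie-break; the folded
    fraction statistic is unaffected).
    """
    snps = passing_snp_fractions(allele_counts, config)
    if not len(snps):
        return pd.DataFrame(columns=["line_id", "gene_id", "primary_allele"])
    sums = snps.groupby(["line_id", "gene_id"], sort=True)[
        ["allele_a_count", "allele_b_count"]
    ].sum()
    primary = np.where(sums["allele_b_count"] > sums["allele_a_count"], "allele_b", "allele_a")
    out = sums.reset_index()[["line_id", "gene_id"]]
    out["primary_allele"] = primary
    return out
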