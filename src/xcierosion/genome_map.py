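"""Chromosome- and cytoband-level aggregation of gene statistics, and
RNA-versus-protein comparisons.

Percentages of significant genes are reported half-up rounded to one
decimal (the convention of the reported headline numbers); the unrounded
fraction is kept alongside, because rounding conventions can disagree at
the last digit.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .utils import percent

logger = logging.getLogger(__name__)


def de_percentages(n_up: int, n_down: int, n_total: int) -> tuple[float, float]:
    """(pct_up, pct_down), half-up rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_up + n_down > n_total:
        raise ValueError("up + down counts exceed the total")
    return percent(n_up, n_total), percent(n_down, n_total)


def summarize_by_chromosome(
    de_rna: pd.DataFrame,
    de_protein: pd.DataFrame,
    annotation: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome medians/SEMs of log2 fold changes on each layer, the
    Pearson correlation between the layers' fold changes, and significant
    up/down counts — restricted to genes present in both layers.

    A chromosome with fewer than 3 shared genes with finite fold changes on
    both layers gets a missing correlation; medians are still emitted.
    """
    chrom_of = annotation.set_index("gene_id")["chromosome"]
    shared = de_rna.index.intersection(de_protein.index)
    rows = []
    for chrom in pd.unique(chrom_of.reindex(shared).dropna()):
        genes = [g for g in shared if chrom_of.get(g) == chrom]
        fc_rna = de_rna.loc[genes, "log2_fc"]
        fc_prot = de_protein.loc[genes, "log2_fc"]
        both = np.isfinite(fc_rna.to_numpy()) & np.isfinite(fc_prot.to_numpy())
        if both.sum() >= 3 and fc_rna[both].nunique() > 1 and fc_prot[both].nunique() > 1:
            r = float(stats.pearsonr(fc_rna[both], fc_prot[both]).statistic)
        else:
            r = np.nan
        for layer, table in (("rna", de_rna), ("protein", de_protein)):
            fc = table.loc[genes, "log2_fc"].dropna()
            n_total = int(table.loc[genes, "q_value"].notna().sum())
            n_up = int(((table.loc[genes, "q_value"] <= q_threshold) & (table.loc[genes, "log2_fc"] > 0)).sum())
            n_down = int(((table.loc[genes, "q_value"] <= q_threshold) & (table.loc[genes, "log2_fc"] < 0)).sum())
            pct_up, pct_down = de_percentages(n_up, n_down, n_total) if n_total else (np.nan, np.nan)
            rows.append(
                {
                    "chromosome": chrom,
                    "layer": layer,
                    "median_log2_fc": float(np.median(fc)) if len(fc) else np.nan,
                    "sem": float(fc.std(ddof=1) / np.sqrt(len(fc))) if len(fc) > 1 else np.nan,
                    "n_genes": int(len(fc)),
                    "pearson_r_rna_vs_protein_fc": r,
                    "n_up": n_up,
                    "n_down": n_down,
                    "n_total": n_total,
                    "pct_up": pct_up,
                    "pct_down": pct_down,
                }
            )
    out = pd.DataFrame(rows)
    order = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}
    return out.sort_values(["chromosome", "layer"], key=lambda s: s.map(lambda v: order.get(v, v))).reset_index(drop=True)


def band_summary(values: pd.Series, annotation: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Median of a per-gene metric per cytoband, with gene counts.

    Genes without a cytoband are excluded (their count is logged).
    """
    band_of = annotation.set_index("gene_id")["cytoband"].replace("", np.nan)
    df = pd.DataFrame({"value": values})
    df["cytoband"] = df.index.map(band_of)
    dropped = int(df["cytoband"].isna().sum() + df["value"].isna().sum())
    if dropped:
        logger.info("band_summary: excluded %d unmapped or missing gene value(s)", dropped)
    df = df.dropna()
    out = (
        df.groupby("cytoband")["value"]
        .agg(median_value="median", n_genes="size")
        .reset_index()
    )
    out.insert(1, "metric", metric)
    out["n_genes"] = out["n_genes"].astype(int)
    return out


def rna_protein_abundance_correlation(
    rna: pd.DataFrame,
    copies: pd.DataFrame,
    gene_to_accession: pd.Series,
    log2_pseudocount: float = 0.01,
) -> tuple[float, int]:
    """Pearson r of per-gene median log2 TPM versus median log10 copies.

    ``gene_to_accession`` maps the RNA matrix's gene ids to copy-matrix row
    ids.  Returns (r, number of shared genes).
    """
    mapping = gene_to_accession[gene_to_accession.isin(copies.index)]
    genes = rna.index.intersection(mapping.index)
    if len(genes) < 3:
        raise ValueError("fewer than 3 genes shared between the two layers")
    med_rna = np.log2(rna.loc[genes].median(axis=1) + log2_pseudocount)
    with np.errstate(divide="ignore"):
        med_cop = np.log10(copies.loc[mapping[genes]].median(axis=1)).to_numpy()
    ok = np.isfinite(med_rna.to_numpy()) & np.isfinite(med_cop)
    x, y = med_rna.to_numpy()[ok], med_cop[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("abundance correlation undefined: fewer than 3 points or a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    return r, int(ok.sum())
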