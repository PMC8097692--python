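"""Minimal matplotlib renderings of the pipeline's headline views."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def volcano(de_table: pd.DataFrame, chrom_of_gene: pd.Series, path) -> None:
    """log2 fold change versus -log10 p, X-linked genes highlighted."""
    fc = de_table["log2_fc"]
    logp = -np.log10(de_table["p_value"].clip(lower=1e-300))
    is_x = de_table.index.map(lambda g: chrom_of_gene.get(g) == "X")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(fc[~is_x], logp[~is_x], s=4, c="grey", alpha=0.5, label="autosome")
    ax.scatter(fc[is_x], logp[is_x], s=6, c="red", alpha=0.7, label="X")
    ax.axhline(-np.log10(0.05), color="orange", lw=1)
    ax.set_xlabel("log2 fold change (low/high XIST)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def content_boxplot(content: pd.Series, groups: dict, path) -> None:
    """Per-line protein content by group."""
    data = [content[lines].dropna() for lines in groups.values()]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(data, tick_labels=list(groups))
    ax.set_ylabel("protein content (pg per cell)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
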