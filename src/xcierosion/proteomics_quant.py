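"""Absolute protein quantification: QC filtering, the histone proteomic
ruler, TMT-plex batch correction, per-cell protein content and ribosome
subunit stoichiometry.

The proteomic ruler anchors the summed histone reporter signal of a line to
the (essentially constant) DNA mass of a diploid cell:

    copies(i, j) = I(i, j) * m_DNA * N_A / ( MW_i * sum_histones I(h, j) )

so copy numbers are invariant to any per-line rescaling of all intensities
(sample loading, labelling efficiency) and the summed histone mass per line
equals ``dna_mass_per_cell_pg`` exactly.

The plex batch correction multiplies every copy number of a plex by
``grand median(per-line protein mass) / median(per-line protein mass of the
plex)``.  It preserves within-plex ratios exactly and is idempotent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23


@dataclass
class RulerConfig:
    dna_mass_per_cell_pg: float = 6.5  # diploid human genome
    min_rup: int = 3
    avogadro: float = AVOGADRO

    def __post_init__(self):
        if self.dna_mass_per_cell_pg <= 0:
            raise ValueError("dna_mass_per_cell_pg must be positive")
        if self.min_rup < 1:
            raise ValueError("min_rup must be >= 1")


def filter_protein_groups(table: pd.DataFrame, config: RulerConfig | None = None) -> pd.DataFrame:
    """Drop contaminant/reverse/only-site rows, then rows with too few
    Razor + unique peptides (default < 3).  Row order is preserved."""
    config = config or RulerConfig()
    keep = ~(table["is_contaminant"] | table["is_reverse"] | table["is_only_site"])
    keep &= table["razor_unique_peptides"] >= config.min_rup
    out = table.loc[keep].copy()
    out.attrs.update(table.attrs)
    return out


def histone_mask(table: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Histone rows of a protein-group table.

    Annotation-driven (rows whose accession is flagged ``histone``), with a
    gene-name family fallback (H1*/H2A*/H2B*/H3*/H4*) so that tables with a
    sparse annotation still find their anchors.
    """
    accs = set(io_formats.set_members(annotation, "histone", key="protein_accession"))
    by_acc = table["accessions"].str.split(";").apply(lambda xs: any(x in accs for x in xs))
    by_name = table["gene_name"].str.match(r"^H(1|2A|2B|3|4)", na=False)
    return by_acc | by_name


def ruler_copy_numbers(
    table: pd.DataFrame,
    annotation: pd.DataFrame,
    config: RulerConfig | None = None,
) -> pd.DataFrame:
    """Protein x line copies per cell via the histone proteomic ruler.

    Missing intensities give missing copies.  A line whose histone signal is
    zero or entirely missing cannot be anchored and raises an error naming
    the line.
    """
    config = config or RulerConfig()
    hist = histone_mask(table, annotation)
    if not hist.any():
        raise ValueError("no histone rows found; the ruler needs at least one anchor")
    intensities = io_formats.protein_group_intensities(table)
    hist_sum = intensities.loc[hist].sum(axis=0, skipna=True)
    bad = hist_sum[(hist_sum <= 0) | hist_sum.isna()]
    if len(bad):
        raise ValueError(f"zero histone signal for line(s): {bad.index.tolist()}")
    dna_g = config.dna_mass_per_cell_pg * 1e-12
    factor = dna_g * config.avogadro / table["mw_da"]
    copies = intensities.div(hist_sum, axis=1).mul(factor, axis=0)
    copies.attrs["table_kind"] = "expression_matrix"
    copies.attrs["layer"] = "protein_copies"
    return copies


def protein_content_pg(copies: pd.DataFrame, mw_da: pd.Series) -> pd.Series:
    """Per-line protein content in picograms: sum_i copies * MW / N_A * 1e12,
    skipping missing values."""
    mw = mw_da.reindex(copies.index)
    mass = copies.mul(mw, axis=0) / AVOGADRO * 1e12
    return mass.sum(axis=0, skipna=True)


def batch_correct(
    copies: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    mw_da: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Equalise the median per-line protein mass across TMT plexes.

    Returns the corrected matrix and the per-plex factors applied.
    """
    plex_of = sample_sheet.set_index("line_id")["tmt_plex"]
    unassigned = [l for l in copies.columns if l not in plex_of.index]
    if unassigned:
        raise ValueError(f"line(s) without a plex assignment: {unassigned}")
    mass = protein_content_pg(copies, mw_da)
    if (mass <= 0).any():
        zero = mass.index[mass <= 0].tolist()
        raise ValueError(f"zero protein mass for line(s): {zero}")
    grand = float(np.median(mass))
    factors = {}
    corrected = copies.copy()
    for plex, lines in plex_of.groupby(plex_of).groups.items():
        lines = [l for l in lines if l in copies.columns]
        if not lines:
            continue
        f = grand / float(np.median(mass[lines]))
        factors[plex] = f
        corrected[lines] = corrected[lines] * f
    factors = pd.Series(factors, name="plex_factor").sort_index()
    logger.info("plex batch factors: %s", factors.to_dict())
    corrected.attrs.update(copies.attrs)
    return corrected, factors


def subunit_ratio(
    copies: pd.DataFrame,
    annotation: pd.DataFrame,
    set_a: str = "ribosome_60S",
    set_b: str = "ribosome_40S",
) -> pd.Series:
    """Per-line ratio of summed copies of two protein sets (default 60S/40S).

    Lines with a zero denominator get NaN and a logged warning.
    """
    acc_a = io_formats.set_members(annotation, set_a, key="protein_accession")
    acc_b = io_formats.set_members(annotation, set_b, key="protein_accession")
    rows_a = copies.index.intersection(acc_a)
    rows_b = copies.index.intersection(acc_b)
    if not len(rows_a) or not len(rows_b):
        raise ValueError(f"empty protein set in copies matrix: {set_a if not len(rows_a) else set_b}")
    num = copies.loc[rows_a].sum(axis=0, skipna=True)
    den = copies.loc[rows_b].sum(axis=0, skipna=True)
    ratio = num / den
    if (den == 0).any():
        logger.warning("zero %s signal for line(s): %s", set_b, den.index[den == 0].tolist())
        ratio[den == 0] = np.nan
    return ratio


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample t: statistic, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t needs at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def group_content_summary(content: pd.Series, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Pairwise percent difference of median per-line content, with Welch p.

    ``percent_difference`` of (A, B) is 100 * (median_A - median_B) /
    median_B.  Groups of fewer than 2 lines are rejected (their variance is
    undefined).
    """
    values = {}
    for name, lines in groups.items():
        present = [l for l in lines if l in content.index]
        vals = content[present].dropna()
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 lines with content")
        values[name] = vals.to_numpy()
    rows = []
    names = list(values)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            med_a, med_b = np.median(values[a]), np.median(values[b])
            t, df, p = welch_t(values[a], values[b])
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "median_a": med_a,
                    "median_b": med_b,
                    "percent_difference": 100.0 * (med_a - med_b) / med_b,
                    "welch_t": t,
                    "welch_df": df,
                    "welch_p": p,
                    "n_a": len(values[a]),
                    "n_b": len(values[b]),
                }
            )
    return pd.DataFrame(rows)
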