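"""XIST stratification of female lines, and plex-replicate capping.

Female lines are split on log2(XIST TPM + pseudocount): strictly below the
low threshold (default 1.0) -> "Low", strictly above the high threshold
(default 2.75) -> "High", otherwise "Medium".  Values exactly on a
threshold fall to Medium, because the thresholds are strict inequalities.

Because the High-XIST population can be dominated by a few TMT plexes, the
High set is optionally capped: any plex contributing more than
``max_lines_per_plex`` (default 4) High lines is reduced by hierarchical
clustering of the lines' copy-number profiles (average linkage on
1 - Pearson correlation of log10 copies), cutting at k = cap and retaining
each cluster's medoid.  Ties break lexicographically on line_id.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class StratifyConfig:
    low_threshold_log2tpm: float = 1.0
    high_threshold_log2tpm: float = 2.75
    max_lines_per_plex: int = 4
    log2_pseudocount: float = 0.01
    xist_gene: str = "XIST"

    def __post_init__(self):
        if not self.low_threshold_log2tpm < self.high_threshold_log2tpm:
            raise ValueError("low threshold must be below high threshold")
        if self.max_lines_per_plex < 1:
            raise ValueError("max_lines_per_plex must be >= 1")


def stratify_by_xist(
    rna: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    config: StratifyConfig | None = None,
) -> pd.DataFrame:
    """Assign Low/Medium/High XIST strata to every female line.

    Returns a frame indexed by line_id with columns ``stratum`` and
    ``log2_xist``.  Male lines are excluded: XCI stratification is only
    meaningful with two X copies.
    """
    config = config or StratifyConfig()
    if config.xist_gene not in rna.index:
        raise ValueError(f"expression matrix has no row for gene {config.xist_gene!r}")
    females = sample_sheet.loc[sample_sheet["donor_sex"] == "female", "line_id"]
    missing = [l for l in females if l not in rna.columns]
    if missing:
        raise ValueError(f"female line(s) missing from expression matrix: {missing}")
    log2 = np.log2(rna.loc[config.xist_gene, females].astype(float) + config.log2_pseudocount)
    stratum = pd.Series("Medium", index=log2.index, name="stratum")
    stratum[log2 < config.low_threshold_log2tpm] = "Low"
    stratum[log2 > config.high_threshold_log2tpm] = "High"
    out = pd.DataFrame({"stratum": stratum, "log2_xist": log2})
    out.index.name = "line_id"
    return out


def stratum_lines(assignment: pd.DataFrame, stratum: str) -> list[str]:
    return assignment.index[assignment["stratum"] == stratum].tolist()


def _medoid(lines: list[str], dist: pd.DataFrame) -> str:
    sub = dist.loc[lines, lines]
    total = sub.sum(axis=1)
    # idxmin on a lexicographically sorted index breaks ties toward the
    # smallest line_id
    return total.loc[sorted(lines)].idxmin()


def cap_plex_replicates(
    high_lines: list[str],
    copies: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    config: StratifyConfig | None = None,
) -> pd.DataFrame:
    """Reduce over-represented plexes in the High-XIST set.

    Returns a frame indexed by line_id with a boolean ``retained_high``
    column.  Lines lacking a copy-number profile are dropped with a logged
    warning.  The operation never increases any plex's count and is
    idempotent.
    """
    config = config or StratifyConfig()
    plex_of = sample_sheet.set_index("line_id")["tmt_plex"]
    missing_profile = [l for l in high_lines if l not in copies.columns]
    if missing_profile:
        logger.warning("dropping %d High line(s) without protein data: %s",
                       len(missing_profile), missing_profile)
    usable = [l for l in high_lines if l in copies.columns]
    retained: set[str] = set()
    by_plex: dict[str, list[str]] = {}
    for line in usable:
        by_plex.setdefault(plex_of[line], []).append(line)
    for plex in sorted(by_plex):
        lines = sorted(by_plex[plex])
        if len(lines) <= config.max_lines_per_plex:
            retained.update(lines)
            continue
        profile = np.log10(copies[lines].replace(0.0, np.nan))
        profile = profile.dropna(axis=0, how="any")
        corr = np.corrcoef(profile.to_numpy().T)
        dist = pd.DataFrame(1.0 - np.nan_to_num(corr, nan=0.0), index=lines, columns=lines)
        np.fill_diagonal(dist.values, 0.0)
        condensed = squareform(np.maximum(dist.to_numpy(), 0.0), checks=False)
        labels = fcluster(linkage(condensed, method="average"),
                          t=config.max_lines_per_plex, criterion="maxclust")
        kept = {
            _medoid([l for l, lab in zip(lines, labels) if lab == cluster_id], dist)
            for cluster_id in np.unique(labels)
        }
        # tied merge heights can yield fewer than k clusters; top the plex up
        # to the cap in lexicographic line_id order for determinism
        for line in lines:
            if len(kept) >= config.max_lines_per_plex:
                break
            kept.add(line)
        retained.update(kept)
    out = pd.DataFrame(
        {"retained_high": [l in retained for l in usable]},
        index=pd.Index(usable, name="line_id"),
    )
    return out.sort_index()
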