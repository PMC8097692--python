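"""End-to-end orchestration: stratify -> ASE -> quantify -> DE -> genome
map -> enrichment, with a machine-readable JSON report.

Every number in the report is a pure aggregation of the underlying module
operations and can be recomputed by calling them directly.  The report
records the seed, the configurations and (for file inputs) input checksums.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ase, diffexp, enrichment, genome_map, io_formats
from . import proteomics_quant as pq
from . import stratification as strat
from .synthetic_data import CohortBundle
from .utils import percent

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    ase: ase.AseConfig = field(default_factory=ase.AseConfig)
    stratify: strat.StratifyConfig = field(default_factory=strat.StratifyConfig)
    ruler: pq.RulerConfig = field(default_factory=pq.RulerConfig)
    de: diffexp.DEConfig = field(default_factory=diffexp.DEConfig)
    enrichment: enrichment.EnrichmentConfig = field(default_factory=enrichment.EnrichmentConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for name, sub in (
            ("ase", ase.AseConfig),
            ("stratify", strat.StratifyConfig),
            ("ruler", pq.RulerConfig),
            ("de", diffexp.DEConfig),
            ("enrichment", enrichment.EnrichmentConfig),
        ):
            if name in data:
                kwargs[name] = sub(**data[name])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)


@dataclass
class InputTables:
    """The five validated input tables of a cohort."""

    sample_sheet: pd.DataFrame
    allele_counts: pd.DataFrame
    rna: pd.DataFrame
    protein_groups: pd.DataFrame
    annotation: pd.DataFrame
    checksums: dict = field(default_factory=dict)


def load_inputs(
    sample_sheet, allele_counts, rna, protein_groups, annotation
) -> InputTables:
    """Read and validate the five cohort tables from TSV paths."""
    paths = {
        "sample_sheet": sample_sheet,
        "allele_counts": allele_counts,
        "rna": rna,
        "protein_groups": protein_groups,
        "annotation": annotation,
    }
    checksums = {
        name: hashlib.md5(Path(p).read_bytes()).hexdigest() for name, p in paths.items()
    }
    sheet = io_formats.read_sample_sheet(sample_sheet)
    return InputTables(
        sample_sheet=sheet,
        allele_counts=io_formats.read_allele_counts(allele_counts),
        rna=io_formats.read_expression_matrix(rna, layer="rna_tpm"),
        protein_groups=io_formats.read_protein_groups(protein_groups, sheet),
        annotation=io_formats.read_annotation(annotation),
        checksums=checksums,
    )


def _from_bundle(bundle: CohortBundle) -> InputTables:
    return InputTables(
        sample_sheet=bundle.sample_sheet,
        allele_counts=bundle.allele_counts,
        rna=bundle.rna,
        protein_groups=bundle.protein_groups,
        annotation=bundle.annotation,
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"cannot serialise {type(obj)!r}")


def _pct_diff_of_medians(a: pd.Series, b: pd.Series) -> float:
    return float(100.0 * (a.median() - b.median()) / b.median())


def run_pipeline(
    inputs: InputTables | CohortBundle,
    config: PipelineConfig | None = None,
    outdir=None,
    make_plots: bool = False,
) -> dict:
    """Run every stage on a cohort and return the report dictionary.

    If ``outdir`` is given, the report (JSON), the stage tables (TSV) and —
    optionally — diagnostic plots (PNG) are written there.
    """
    config = config or PipelineConfig()
    if isinstance(inputs, CohortBundle):
        inputs = _from_bundle(inputs)
    sheet = inputs.sample_sheet
    males = io_formats.male_lines(sheet)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            name: dataclasses.asdict(getattr(config, name))
            for name in ("ase", "stratify", "ruler", "de", "enrichment")
        },
        "input_checksums": inputs.checksums,
    }

    # --- stratification --------------------------------------------------
    strata = strat.stratify_by_xist(inputs.rna, sheet, config.stratify)
    low = strat.stratum_lines(strata, "Low")
    medium = strat.stratum_lines(strata, "Medium")
    high = strat.stratum_lines(strata, "High")
    n_female = len(strata)
    report["stratification"] = {
        "n_female": n_female,
        "n_male": len(males),
        "counts": {"Low": len(low), "Medium": len(medium), "High": len(high)},
        "percentages": {
            "Low": percent(len(low), n_female),
            "Medium": percent(len(medium), n_female),
            "High": percent(len(high), n_female),
        },
    }

    # --- allele-specific expression --------------------------------------
    gene_ase = ase.gene_ase_fractions(inputs.allele_counts, config.ase)
    chrom_ase = ase.aggregate_ase(
        inputs.allele_counts, inputs.annotation, level="chromosome", config=config.ase
    )
    x_ase = chrom_ase[chrom_ase["key"] == "X"].set_index("line_id")["secondary_fraction"]
    report["ase"] = {
        "median_secondary_fraction": {
            name: (float(x_ase.reindex(lines).dropna().median()) if len(lines) else None)
            for name, lines in (("Low", low), ("Medium", medium), ("High", high))
        },
        "n_lines_with_x_ase": int(x_ase.notna().sum()),
    }

    # --- proteomics quantification ---------------------------------------
    filtered = pq.filter_protein_groups(inputs.protein_groups, config.ruler)
    copies_raw = pq.ruler_copy_numbers(filtered, inputs.annotation, config.ruler)
    copies, plex_factors = pq.batch_correct(copies_raw, sheet, filtered["mw_da"])
    content = pq.protein_content_pg(copies, filtered["mw_da"])
    retained = strat.cap_plex_replicates(high, copies, sheet, config.stratify)
    high_retained = retained.index[retained["retained_high"]].tolist()
    strata["retained_high"] = pd.Series(
        strata.index.isin(high_retained), index=strata.index
    ).where(strata["stratum"] == "High")
    report["quantification"] = {
        "n_protein_groups_quantified": int(len(filtered)),
        "plex_factors": plex_factors.to_dict(),
        "n_high_retained": len(high_retained),
    }

    groups = {"Low": low, "High": high_retained, "Male": males}
    content_summary = pq.group_content_summary(content, groups)
    report["protein_content"] = {
        "median_pg": {g: float(content[ls].median()) for g, ls in groups.items()},
        "comparisons": content_summary.to_dict(orient="records"),
    }

    # X versus autosome copy sums
    chrom_of_acc = inputs.annotation.set_index("protein_accession")["chromosome"]
    chrom = pd.Series(copies.index.map(chrom_of_acc), index=copies.index)
    x_sum = copies.loc[chrom == "X"].sum(axis=0, skipna=True)
    auto_sum = copies.loc[chrom.isin([str(i) for i in range(1, 23)])].sum(axis=0, skipna=True)
    report["copy_sums"] = {
        "x_median": {g: float(x_sum[ls].median()) for g, ls in groups.items()},
        "autosome_median": {g: float(auto_sum[ls].median()) for g, ls in groups.items()},
        "x_pct_low_vs_male": _pct_diff_of_medians(x_sum[low], x_sum[males]),
        "x_pct_low_vs_high": _pct_diff_of_medians(x_sum[low], x_sum[high_retained]),
        "x_pct_high_vs_male": _pct_diff_of_medians(x_sum[high_retained], x_sum[males]),
        "autosome_pct_low_vs_male": _pct_diff_of_medians(auto_sum[low], auto_sum[males]),
        "autosome_pct_low_vs_high": _pct_diff_of_medians(auto_sum[low], auto_sum[high_retained]),
    }

    ratio = pq.subunit_ratio(copies, inputs.annotation)
    ratio_rows = {}
    for name, lines in groups.items():
        vals = ratio[lines].dropna()
        ratio_rows[name] = float(vals.median()) if len(vals) else None
    t, df, p = pq.welch_t(ratio[low].dropna(), ratio[high_retained].dropna())
    report["ribosome"] = {"ratio_60s_40s_median": ratio_rows, "welch_p_low_vs_high": p}

    # --- differential expression ------------------------------------------
    de_rna = diffexp.run_de(inputs.rna, low, high, config.de, layer="rna_tpm")
    de_protein = diffexp.run_de(copies, low, high_retained, config.de, layer="protein_copies")

    acc_of_gene = inputs.annotation.set_index("gene_id")["protein_accession"].replace("", np.nan).dropna()
    gene_of_acc = pd.Series(acc_of_gene.index, index=acc_of_gene.to_numpy())
    de_protein_genes = de_protein.copy()
    de_protein_genes.index = de_protein_genes.index.map(
        lambda a: gene_of_acc.get(a, a)
    )

    chrom_of_gene = inputs.annotation.set_index("gene_id")["chromosome"]
    autosomes = {str(i) for i in range(1, 23)}

    def _layer_counts(table: pd.DataFrame, subset: str) -> dict:
        genes = table.index[table.index.map(lambda g: chrom_of_gene.get(g) in autosomes)] \
            if subset == "autosome" else \
            table.index[table.index.map(lambda g: chrom_of_gene.get(g) == "X")]
        sub = table.loc[genes]
        n_total = int(sub["q_value"].notna().sum())
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        if n_total:
            pct_up, pct_down = genome_map.de_percentages(n_up, n_down, n_total)
        else:
            pct_up = pct_down = None
        return {
            "n_total": n_total, "n_up": n_up, "n_down": n_down,
            "pct_up": pct_up, "pct_down": pct_down,
            "frac_up_unrounded": n_up / n_total if n_total else None,
            "frac_down_unrounded": n_down / n_total if n_total else None,
        }

    report["differential_expression"] = {
        "rna": {"autosome": _layer_counts(de_rna, "autosome"), "x": _layer_counts(de_rna, "x")},
        "protein": {
            "autosome": _layer_counts(de_protein_genes, "autosome"),
            "x": _layer_counts(de_protein_genes, "x"),
        },
    }

    # --- genome map --------------------------------------------------------
    chrom_summary = genome_map.summarize_by_chromosome(
        de_rna, de_protein_genes, inputs.annotation, config.de.q_threshold
    )
    x_rows = chrom_summary[chrom_summary["chromosome"] == "X"]
    auto_r = chrom_summary[
        (chrom_summary["chromosome"] != "X") & (chrom_summary["layer"] == "rna")
    ]["pearson_r_rna_vs_protein_fc"].dropna()
    report["chromosome_summary"] = {
        "x_pearson_r_fc": float(x_rows["pearson_r_rna_vs_protein_fc"].iloc[0]) if len(x_rows) else None,
        "median_autosome_pearson_r_fc": float(auto_r.median()) if len(auto_r) else None,
        "x_median_log2_fc": {
            row["layer"]: row["median_log2_fc"] for _, row in x_rows.iterrows()
        },
    }

    r_abund, n_shared = genome_map.rna_protein_abundance_correlation(
        inputs.rna, copies, acc_of_gene, config.de.log2_pseudocount
    )
    report["rna_protein_abundance"] = {"pearson_r": r_abund, "n_genes": n_shared}

    band_fc_rna = genome_map.band_summary(
        de_rna.loc[de_rna.index.map(lambda g: chrom_of_gene.get(g) == "X"), "log2_fc"],
        inputs.annotation, "log2_fc_rna",
    )

    # --- enrichment --------------------------------------------------------
    detected_both = [
        g for g in de_protein_genes.index
        if g in inputs.rna.index and g in acc_of_gene.index
    ]
    subset = [
        g for g in detected_both
        if de_protein_genes.loc[g, "direction"] == "up" and de_rna.loc[g, "direction"] != "up"
        if g in de_rna.index
    ]
    enr_config = dataclasses.replace(config.enrichment, seed=config.seed)
    report["enrichment"] = {}
    if subset:
        median_copies = copies.loc[acc_of_gene[detected_both]].median(axis=1)
        median_copies.index = detected_both
        rup = filtered.set_index(filtered.index)["razor_unique_peptides"]
        rup_genes = pd.Series(
            rup.reindex(acc_of_gene[detected_both]).to_numpy(), index=detected_both, dtype=float
        )
        for metric_name, values in (("copies", median_copies), ("peptides", rup_genes)):
            res = enrichment.enrichment_analysis(values, subset, enr_config, metric_name)
            report["enrichment"][metric_name] = dataclasses.asdict(res)
        report["enrichment"]["subset_size"] = len(subset)
    else:
        report["enrichment"]["subset_size"] = 0

    # --- outputs -----------------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        strata.to_csv(outdir / "strata.tsv", sep="\t")
        gene_ase.to_csv(outdir / "ase_gene.tsv", sep="\t", index=False)
        chrom_ase.to_csv(outdir / "ase_chromosome.tsv", sep="\t", index=False)
        io_formats.write_table(copies, outdir / "protein_copies.tsv")
        content.rename("protein_content_pg").to_csv(outdir / "protein_content.tsv", sep="\t")
        ratio.rename("ratio_60s_40s").to_csv(outdir / "ratio_60s_40s.tsv", sep="\t")
        de_rna.to_csv(outdir / "de_rna.tsv", sep="\t")
        de_protein.to_csv(outdir / "de_protein.tsv", sep="\t")
        chrom_summary.to_csv(outdir / "chromosome_summary.tsv", sep="\t", index=False)
        band_fc_rna.to_csv(outdir / "band_log2fc_rna.tsv", sep="\t", index=False)
        # gene lists for external overrepresentation tools
        pd.Series(subset, name="gene_id").to_csv(outdir / "protein_only_up_genes.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
        if make_plots:
            from . import plots

            plots.volcano(de_protein_genes, chrom_of_gene, outdir / "volcano_protein.png")
            plots.volcano(de_rna, chrom_of_gene, outdir / "volcano_rna.png")
            plots.content_boxplot(content, groups, outdir / "protein_content.png")
    return report
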