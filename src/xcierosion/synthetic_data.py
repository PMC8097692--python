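"""Synthetic iPSC-cohort generator with configurable XCI-erosion structure.

The generator produces every table the pipeline consumes (sample sheet,
heterozygous-SNP allele counts, TPM matrix, MaxQuant-style protein groups,
gene annotation) together with a ``truth`` record of the injected parameters,
so every downstream stage is testable without any external download.

What the cohort emulates
------------------------
* Bimodal XIST expression over female lines: log2 TPM drawn below 1 for
  "Low" lines, above 2.75 for "High" lines, in between for "Medium".
* Erosion-dependent biallelic expression: per-SNP allele counts are binomial
  with a per-line secondary-allele probability (defaults 0.005 for High /
  Medium and 0.226 for Low lines, the two observed population medians).
* X-linked amplification in eroded (Low-XIST) lines on both the RNA and
  protein layers, with gene-to-gene variation and escape-prone band
  hotspots (Xp22, Xq23, Xq26).
* An autosome-wide, protein-only amplification (a global translation
  factor; default fold 1.13).
* TMT plex structure with multiplicative batch effects applied to the
  non-histone reporter intensities (see the methods note for why a
  histone-relative effect is the recoverable one).
* Histone anchor proteins whose summed mass equals the DNA mass per cell,
  so the proteomic ruler is exact on noiseless data.
* Per-protein measurement noise that shrinks with peptide count, which is
  what couples detectability to abundance.

Male lines carry a single X allele (allele_b_count = 0) and no
amplification; they serve as the dosage-compensation reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .utils import substream

AVOGADRO = 6.02214076e23

# canonical histone families and molecular weights (Da)
_HISTONE_FAMILIES = [
    ("H4C1", 11367.0),
    ("H3C1", 15404.0),
    ("H2AC4", 14105.0),
    ("H2BC5", 13920.0),
    ("H1-1", 21842.0),
]

_X_BANDS = ["Xp22", "Xp11", "Xq13", "Xq21", "Xq23", "Xq26", "Xq28"]
_X_HOTSPOTS = {"Xp22", "Xq23", "Xq26"}
_AUTOSOME_BANDS = ["p11", "p21", "q11", "q21", "q31"]


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults encode the study conditions: 74 female lines split 30/9/35
    into Low/Medium/High XIST, 46 male lines, secondary-allele fractions
    0.226 (Low) vs 0.005 (High), a protein-only autosome fold of 1.13 and
    an X-linked RNA+protein fold of 1.27, TMT 10-plexes with ~10% batch
    effects, and histone ruler anchors.
    """

    n_female_low: int = 30
    n_female_medium: int = 9
    n_female_high: int = 35
    n_male: int = 46
    n_genes_autosome: int = 800
    n_genes_x: int = 40
    n_snps_per_gene: int = 3
    mean_depth: float = 60.0
    secondary_fraction_high: float = 0.005
    secondary_fraction_low: float = 0.226
    x_rna_amplification: float = 1.27
    autosome_protein_amplification: float = 1.13
    plex_size: int = 10
    plex_effect_sd: float = 0.1
    n_histones: int = 5
    noise_sd_rna: float = 0.25
    noise_sd_protein: float = 0.3
    seed: int = 0
    # secondary knobs (realism of scale and coupling; see methods note)
    content_target_pg: float = 200.0
    rna_protein_coupling: float = 0.9
    coupling_noise_ln: float = 1.7
    line_scale_sd: float = 0.2
    dna_mass_per_cell_pg: float = 6.5

    def validate(self) -> None:
        counts = {
            "n_female_low": self.n_female_low,
            "n_female_medium": self.n_female_medium,
            "n_female_high": self.n_female_high,
            "n_male": self.n_male,
            "n_genes_autosome": self.n_genes_autosome,
            "n_genes_x": self.n_genes_x,
            "n_snps_per_gene": self.n_snps_per_gene,
            "plex_size": self.plex_size,
            "n_histones": self.n_histones,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name in ("secondary_fraction_high", "secondary_fraction_low"):
            value = getattr(self, name)
            if not 0.0 <= value <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {value}")
        for name in ("x_rna_amplification", "autosome_protein_amplification"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive fold")
        if self.n_genes_x * self.n_snps_per_gene < 1:
            raise ValueError("configuration implies 0 heterozygous SNPs for female lines")


@dataclass
class CohortTruth:
    """Injected parameters, kept for recovery tests."""

    lines: pd.DataFrame    # line_id, stratum, secondary_fraction, plex, plex_effect, ...
    genes: pd.DataFrame    # gene_id, accession, chromosome, base_tpm, base_copies, ...
    plex_effects: pd.Series
    config: CohortConfig


@dataclass
class CohortBundle:
    sample_sheet: pd.DataFrame
    allele_counts: pd.DataFrame
    rna: pd.DataFrame
    protein_groups: pd.DataFrame
    annotation: pd.DataFrame
    truth: CohortTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_formats.write_table(self.sample_sheet, outdir / "sample_sheet.tsv")
        io_formats.write_table(self.allele_counts, outdir / "allele_counts.tsv")
        io_formats.write_table(self.rna, outdir / "rna_tpm.tsv")
        io_formats.write_table(self.protein_groups, outdir / "protein_groups.tsv")
        io_formats.write_table(self.annotation, outdir / "annotation.tsv")
        self.truth.lines.to_csv(outdir / "truth_lines.tsv", sep="\t", index=False)
        self.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.truth.plex_effects.rename("plex_effect").to_csv(outdir / "truth_plex_effects.tsv", sep="\t")


def _line_table(config: CohortConfig) -> pd.DataFrame:
    strata = (
        ["Low"] * config.n_female_low
        + ["High"] * config.n_female_high
        + ["Medium"] * config.n_female_medium
        + ["Male"] * config.n_male
    )
    n = len(strata)
    n_plex = int(np.ceil(n / config.plex_size))
    rows = []
    for i, stratum in enumerate(strata):
        rows.append(
            {
                "line_id": f"ips{i:03d}",
                "donor_sex": "male" if stratum == "Male" else "female",
                "donor_id": f"donor{i:03d}",
                "tmt_plex": f"plex{(i % n_plex) + 1:02d}",  # round-robin by line order
                "stratum": stratum,
            }
        )
    return pd.DataFrame(rows)


def _gene_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(config.n_genes_autosome):
        chrom = str((i % 22) + 1)
        band = _AUTOSOME_BANDS[(i // 22) % len(_AUTOSOME_BANDS)]
        rows.append(
            {
                "gene_id": f"AG{i + 1:05d}",
                "chromosome": chrom,
                "cytoband": f"{chrom}{band}",
                "is_x": False,
                "is_histone": False,
            }
        )
    for i in range(config.n_genes_x):
        rows.append(
            {
                "gene_id": f"XG{i + 1:05d}",
                "chromosome": "X",
                "cytoband": _X_BANDS[i % len(_X_BANDS)],
                "is_x": True,
                "is_histone": False,
            }
        )
    for i in range(config.n_histones):
        name, mw = _HISTONE_FAMILIES[i % len(_HISTONE_FAMILIES)]
        if i >= len(_HISTONE_FAMILIES):
            name = f"{name}v{i // len(_HISTONE_FAMILIES)}"
        rows.append(
            {
                "gene_id": name,
                "chromosome": "6",
                "cytoband": "6p21",  # the major histone cluster
                "is_x": False,
                "is_histone": True,
            }
        )
    genes = pd.DataFrame(rows)
    genes["accession"] = [f"P{i + 1:05d}" for i in range(len(genes))]

    # molecular weights: log-normal around 50 kDa; histones canonical
    mw = np.exp(rng.normal(np.log(50e3), 0.4, size=len(genes)))
    hist_mask = genes["is_histone"].to_numpy()
    mw[hist_mask] = [
        _HISTONE_FAMILIES[i % len(_HISTONE_FAMILIES)][1] for i in range(config.n_histones)
    ]
    genes["mw_da"] = mw

    # baseline RNA abundance and coupled protein abundance
    ln_tpm = rng.normal(np.log(20.0), 1.5, size=len(genes))
    ln_copies = (
        np.log(1e6)
        + config.rna_protein_coupling * (ln_tpm - np.log(20.0))
        + rng.normal(0.0, config.coupling_noise_ln, size=len(genes))
    )
    genes["base_tpm"] = np.exp(ln_tpm)
    base_copies = np.exp(ln_copies)

    # rescale non-histone copies so the reference proteome mass is realistic
    nonhist = ~hist_mask
    mass_pg = (base_copies[nonhist] * mw[nonhist]).sum() / AVOGADRO * 1e12
    base_copies[nonhist] *= config.content_target_pg / mass_pg
    # histone anchors: equal mass split of the DNA mass per cell
    mass_per_histone_g = config.dna_mass_per_cell_pg * 1e-12 / config.n_histones
    base_copies[hist_mask] = mass_per_histone_g * AVOGADRO / mw[hist_mask]
    genes["base_copies"] = base_copies

    # peptide counts grow with abundance (big/abundant proteins yield more
    # peptides); histone anchors are saturated, extremely well-covered rows
    lam = 1.5 + 2.2 * np.maximum(0.0, np.log10(base_copies) - 4.0)
    rup = 1 + rng.poisson(lam)
    rup[hist_mask] = 30 + rng.poisson(8.0, size=hist_mask.sum())
    genes["razor_unique_peptides"] = rup

    # X-linked escape propensity: band hotspots plus gene-level variation,
    # normalised so the configured fold is the mean log-fold over X genes
    w = rng.gamma(16.0, 1.0 / 16.0, size=len(genes))
    w *= np.where(genes["cytoband"].isin(_X_HOTSPOTS), 1.5, 0.9)
    is_x_arr = genes["is_x"].to_numpy()
    if is_x_arr.any():
        w = w / w[is_x_arr].mean()
    amp = np.where(is_x_arr, np.exp(np.log(config.x_rna_amplification) * w), 1.0)
    genes["x_amplification"] = amp

    # functional sets drawn from autosomal, non-histone genes
    pool = genes.index[nonhist & ~genes["is_x"].to_numpy()]
    picks = rng.choice(pool, size=min(24, len(pool)), replace=False)
    genes["ribosome_60S"] = genes.index.isin(picks[:8])
    genes["ribosome_40S"] = genes.index.isin(picks[8:14])
    genes["ribosome_biogenesis"] = genes.index.isin(picks[14:24])
    return genes


def _xist_tpm(truth_lines: pd.DataFrame, rng: np.random.Generator) -> pd.Series:
    """Bimodal XIST TPM per line, respecting the stratification bands."""
    log2 = np.empty(len(truth_lines))
    stratum = truth_lines["stratum"].to_numpy()
    log2[stratum == "Low"] = rng.uniform(-2.0, 0.9, (stratum == "Low").sum())
    log2[stratum == "Medium"] = rng.uniform(1.2, 2.6, (stratum == "Medium").sum())
    log2[stratum == "High"] = rng.uniform(3.0, 5.5, (stratum == "High").sum())
    log2[stratum == "Male"] = rng.uniform(-5.0, -2.0, (stratum == "Male").sum())
    return pd.Series(2.0 ** log2, index=truth_lines["line_id"])


def generate_cohort(config: CohortConfig | None = None, **overrides) -> CohortBundle:
    """Generate a complete synthetic cohort; deterministic given ``config.seed``."""
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    config.validate()
    seed = config.seed

    lines = _line_table(config)
    genes = _gene_table(config, substream(seed, "genes"))

    sec_by_stratum = {
        "Low": config.secondary_fraction_low,
        "Medium": config.secondary_fraction_high,
        "High": config.secondary_fraction_high,
        "Male": 0.0,
    }
    lines["secondary_fraction"] = lines["stratum"].map(sec_by_stratum)

    plex_ids = sorted(lines["tmt_plex"].unique())
    rng_plex = substream(seed, "plex")
    plex_effects = pd.Series(
        np.exp(rng_plex.normal(0.0, config.plex_effect_sd, size=len(plex_ids))), index=plex_ids
    )
    lines["plex_effect"] = lines["tmt_plex"].map(plex_effects)
    rng_scale = substream(seed, "line_scale")
    lines["line_scale"] = np.exp(rng_scale.normal(0.0, config.line_scale_sd, size=len(lines)))
    lines["xist_tpm"] = _xist_tpm(lines, substream(seed, "xist")).to_numpy()

    sample_sheet = lines[["line_id", "donor_sex", "tmt_plex", "donor_id"]].copy()
    sample_sheet.attrs["table_kind"] = "sample_sheet"

    # --- RNA layer -------------------------------------------------------
    rng_rna = substream(seed, "rna")
    is_low = (lines["stratum"] == "Low").to_numpy()
    amp_rna = np.where(
        is_low[None, :], genes["x_amplification"].to_numpy()[:, None], 1.0
    )
    noise = np.exp(rng_rna.normal(0.0, config.noise_sd_rna, size=(len(genes), len(lines))))
    tpm = genes["base_tpm"].to_numpy()[:, None] * amp_rna * noise
    rna = pd.DataFrame(tpm, index=genes["gene_id"], columns=lines["line_id"])
    rna.loc["XIST"] = lines["xist_tpm"].to_numpy()
    rna = io_formats.validate_expression_matrix(rna, layer="rna_tpm", source="generator")

    # --- allele counts (X genes, XIST excluded) --------------------------
    rng_ase = substream(seed, "allele_counts")
    x_genes = genes[genes["is_x"]]
    rows = []
    for gi, gene in enumerate(x_genes.itertuples()):
        for line in lines.itertuples():
            flip = rng_ase.random() < 0.5
            for s in range(config.n_snps_per_gene):
                depth = int(rng_ase.poisson(config.mean_depth))
                if line.donor_sex == "male":
                    secondary = 0
                else:
                    secondary = int(rng_ase.binomial(depth, line.secondary_fraction)) if depth else 0
                primary = depth - secondary
                a, b = (secondary, primary) if flip else (primary, secondary)
                rows.append(
                    {
                        "contig": "X",
                        "position": (gi + 1) * 1_000_000 + s * 100 + 1,
                        "gene_id": gene.gene_id,
                        "line_id": line.line_id,
                        "allele_a_count": a,
                        "allele_b_count": b,
                    }
                )
    allele_counts = io_formats.validate_allele_counts(pd.DataFrame(rows), source="generator")

    # --- protein layer ---------------------------------------------------
    rng_prot = substream(seed, "protein")
    hist = genes["is_histone"].to_numpy()
    amp_prot = np.where(
        is_low[None, :],
        np.where(
            genes["is_x"].to_numpy()[:, None],
            genes["x_amplification"].to_numpy()[:, None],
            np.where(hist[:, None], 1.0, config.autosome_protein_amplification),
        ),
        1.0,
    )
    copies_truth = genes["base_copies"].to_numpy()[:, None] * amp_prot
    # measurement noise shrinks with peptide count
    sd = config.noise_sd_protein * np.sqrt(3.0 / np.maximum(genes["razor_unique_peptides"].to_numpy(), 3))
    noise_p = np.exp(rng_prot.normal(0.0, 1.0, size=copies_truth.shape) * sd[:, None])
    plex_vec = lines["plex_effect"].to_numpy()
    batch = np.where(hist[:, None], 1.0, plex_vec[None, :])  # histone-relative plex effect
    intensity = (
        copies_truth
        * genes["mw_da"].to_numpy()[:, None]
        * batch
        * lines["line_scale"].to_numpy()[None, :]
        * noise_p
    )

    pg = pd.DataFrame(
        {
            "accessions": genes["accession"].to_numpy(),
            "gene_name": genes["gene_id"].to_numpy(),
            "mw_da": genes["mw_da"].to_numpy(),
            "razor_unique_peptides": genes["razor_unique_peptides"].to_numpy(),
            "is_contaminant": False,
            "is_reverse": False,
            "is_only_site": False,
        }
    )
    pg = pd.concat(
        [pg, pd.DataFrame(intensity, columns=lines["line_id"].tolist())], axis=1
    )
    # decoy / contaminant rows so the QC filter has something to remove
    decoys = pd.DataFrame(
        {
            "accessions": ["CON__P99991", "REV__P99992", "P99993"],
            "gene_name": ["KRT1", "", "SITEONLY1"],
            "mw_da": [66000.0, 30000.0, 45000.0],
            "razor_unique_peptides": [12, 2, 4],
            "is_contaminant": [True, False, False],
            "is_reverse": [False, True, False],
            "is_only_site": [False, False, True],
        }
    )
    rng_decoy = substream(seed, "decoys")
    decoys = pd.concat(
        [
            decoys,
            pd.DataFrame(
                np.exp(rng_decoy.normal(np.log(1e9), 0.5, size=(3, len(lines)))),
                columns=lines["line_id"].tolist(),
            ),
        ],
        axis=1,
    )
    pg = pd.concat([pg, decoys], ignore_index=True)
    protein_groups = io_formats.validate_protein_groups(
        pg, lines["line_id"].tolist(), source="generator"
    )

    # --- annotation ------------------------------------------------------
    ann = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "protein_accession": genes["accession"],
            "chromosome": genes["chromosome"],
            "cytoband": genes["cytoband"],
            "ribosome_60S": genes["ribosome_60S"],
            "ribosome_40S": genes["ribosome_40S"],
            "ribosome_biogenesis": genes["ribosome_biogenesis"],
            "histone": genes["is_histone"],
        }
    )
    ann = pd.concat(
        [
            ann,
            pd.DataFrame(
                [
                    {
                        "gene_id": "XIST",
                        "protein_accession": "",
                        "chromosome": "X",
                        "cytoband": "Xq13",
                        "ribosome_60S": False,
                        "ribosome_40S": False,
                        "ribosome_biogenesis": False,
                        "histone": False,
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    annotation = io_formats.validate_annotation(ann, source="generator")

    truth = CohortTruth(
        lines=lines,
        genes=genes,
        plex_effects=plex_effects,
        config=config,
    )
    return CohortBundle(sample_sheet, allele_counts, rna, protein_groups, annotation, truth)


def generate_null_cohort(config: CohortConfig | None = None, **overrides) -> CohortBundle:
    """As :func:`generate_cohort` but with all effects nulled.

    Amplification folds are forced to 1 and the secondary-allele fraction is
    equal across strata, so any downstream discovery is a false positive;
    used for type-I-error calibration.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    null_config = replace(
        config,
        x_rna_amplification=1.0,
        autosome_protein_amplification=1.0,
        secondary_fraction_low=config.secondary_fraction_high,
    )
    return generate_cohort(null_config)
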