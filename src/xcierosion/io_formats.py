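"""Readers and writers for the cohort's tabular formats, with strict schemas.

Five table kinds flow through the pipeline:

* sample sheet        — one row per iPSC line (sex, donor, TMT plex),
* allele counts       — heterozygous-SNP read counts for two alleles,
* expression matrix   — gene x line grid (TPM or protein copies per cell),
* gene annotation     — gene <-> protein accession, chromosome, cytoband,
                        functional-set flags (60S, 40S, ribosome biogenesis,
                        histone),
* protein groups      — MaxQuant ``proteinGroups.txt``-like rows with one
                        reporter-intensity column per line.

All tables are plain TSV with a header.  Protein groups mirror the MaxQuant
column names where they exist ("Razor + unique peptides", "Potential
contaminant", ...); reporter columns are named
``Reporter intensity corrected <line_id>``.  Positions are 1-based.
Missing reporter intensities are kept as missing (NaN), never coerced to 0,
because zeros would silently enter ruler sums.

Writers emit a fixed column order and floats at 6 significant digits, so a
given table always serialises to the identical file.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.6g"

VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

SAMPLE_SHEET_COLUMNS = ["line_id", "donor_sex", "tmt_plex", "donor_id"]
ALLELE_COUNT_COLUMNS = [
    "contig",
    "position",
    "gene_id",
    "line_id",
    "allele_a_count",
    "allele_b_count",
]
ANNOTATION_SET_COLUMNS = ["ribosome_60S", "ribosome_40S", "ribosome_biogenesis", "histone"]
ANNOTATION_COLUMNS = ["gene_id", "protein_accession", "chromosome", "cytoband"] + ANNOTATION_SET_COLUMNS

# MaxQuant-style protein-group columns.
MQ_ACCESSIONS = "Majority protein IDs"
MQ_GENE = "Gene names"
MQ_MW_KDA = "Mol. weight [kDa]"
MQ_RUP = "Razor + unique peptides"
MQ_CONTAMINANT = "Potential contaminant"
MQ_REVERSE = "Reverse"
MQ_ONLY_SITE = "Only identified by site"
MQ_INTENSITY_PREFIX = "Reporter intensity corrected "
PROTEIN_GROUP_META = [
    "accessions",
    "gene_name",
    "mw_da",
    "razor_unique_peptides",
    "is_contaminant",
    "is_reverse",
    "is_only_site",
]


class SchemaError(ValueError):
    """An input table violates its declared schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, SAMPLE_SHEET_COLUMNS, path)
    df = df[SAMPLE_SHEET_COLUMNS].copy()
    if df["line_id"].duplicated().any():
        dup = df.loc[df["line_id"].duplicated(), "line_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate line_id {dup!r}")
    bad = set(df["donor_sex"]) - {"female", "male"}
    if bad:
        raise SchemaError(f"{path}: donor_sex must be female/male, got {sorted(bad)}")
    df.attrs["table_kind"] = "sample_sheet"
    return df


def female_lines(sample_sheet: pd.DataFrame) -> list[str]:
    return sample_sheet.loc[sample_sheet["donor_sex"] == "female", "line_id"].tolist()


def male_lines(sample_sheet: pd.DataFrame) -> list[str]:
    return sample_sheet.loc[sample_sheet["donor_sex"] == "male", "line_id"].tolist()


# ---------------------------------------------------------------------------
# allele counts


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "gene_id": str, "line_id": str})
    _require_columns(df, ALLELE_COUNT_COLUMNS, path)
    df = df[ALLELE_COUNT_COLUMNS].copy()
    return validate_allele_counts(df, source=path)


def validate_allele_counts(df: pd.DataFrame, source="allele counts") -> pd.DataFrame:
    for col in ("position", "allele_a_count", "allele_b_count"):
        values = pd.to_numeric(df[col], errors="raise")
        if (values != values.astype(int)).any():
            raise SchemaError(f"{source}: column {col!r} must be integer")
        df[col] = values.astype(int)
    if (df["position"] < 1).any():
        raise SchemaError(f"{source}: positions are 1-based; found position < 1")
    if (df[["allele_a_count", "allele_b_count"]] < 0).any().any():
        raise SchemaError(f"{source}: negative allele count")
    key = df[["contig", "position", "line_id"]]
    if key.duplicated().any():
        row = key[key.duplicated()].iloc[0]
        raise SchemaError(
            f"{source}: duplicate (contig, position, line_id) = "
            f"({row['contig']}, {row['position']}, {row['line_id']})"
        )
    df.attrs["table_kind"] = "allele_counts"
    return df


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path, layer: str = "rna_tpm") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_expression_matrix(df, layer=layer, source=path)


def validate_expression_matrix(df: pd.DataFrame, layer: str = "rna_tpm", source="matrix") -> pd.DataFrame:
    if layer not in ("rna_tpm", "protein_copies"):
        raise SchemaError(f"{source}: unknown layer {layer!r}")
    if df.index.duplicated().any():
        raise SchemaError(f"{source}: duplicate row label {df.index[df.index.duplicated()][0]!r}")
    if df.columns.duplicated().any():
        raise SchemaError(f"{source}: duplicate column label")
    values = df.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise SchemaError(f"{source}: negative values are not allowed in an expression matrix")
    df = df.astype(float)
    df.index.name = "gene_id"
    df.columns.name = None
    df.attrs["table_kind"] = "expression_matrix"
    df.attrs["layer"] = layer
    return df


# ---------------------------------------------------------------------------
# gene annotation


def _check_cytoband(chromosome: str, cytoband: str) -> bool:
    if cytoband == "":
        return True  # unplaced gene; allowed, excluded from band summaries
    if not cytoband.startswith(chromosome):
        return False
    rest = cytoband[len(chromosome):]
    return len(rest) > 0 and rest[0] in ("p", "q")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "protein_accession": str, "chromosome": str, "cytoband": str},
        keep_default_na=False,
    )
    _require_columns(df, ANNOTATION_COLUMNS, path)
    df = df[ANNOTATION_COLUMNS].copy()
    return validate_annotation(df, source=path)


def validate_annotation(df: pd.DataFrame, source="annotation") -> pd.DataFrame:
    df = df.copy()
    df["cytoband"] = df["cytoband"].fillna("").astype(str)
    df["protein_accession"] = df["protein_accession"].fillna("").astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    unknown = set(df["chromosome"]) - set(VALID_CHROMOSOMES)
    if unknown:
        raise SchemaError(f"{source}: unknown chromosome label(s) {sorted(unknown)}")
    for _, row in df.iterrows():
        if not _check_cytoband(row["chromosome"], row["cytoband"]):
            raise SchemaError(
                f"{source}: cytoband {row['cytoband']!r} does not match "
                f"chromosome {row['chromosome']!r} for gene {row['gene_id']!r}"
            )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise SchemaError(f"{source}: duplicate gene_id {dup!r}")
    for col in ANNOTATION_SET_COLUMNS:
        df[col] = df[col].astype(int).astype(bool)
    df.attrs["table_kind"] = "annotation"
    return df


def set_members(annotation: pd.DataFrame, set_name: str, key: str = "gene_id") -> list[str]:
    """Identifiers (gene_id or protein_accession) of a functional set."""
    if set_name not in ANNOTATION_SET_COLUMNS:
        raise ValueError(f"unknown functional set {set_name!r}")
    sel = annotation.loc[annotation[set_name], key]
    return [v for v in sel.tolist() if v != ""]


# ---------------------------------------------------------------------------
# protein groups


def read_protein_groups(path, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={MQ_ACCESSIONS: str, MQ_GENE: str}, keep_default_na=False)
    mandatory = [MQ_ACCESSIONS, MQ_GENE, MQ_MW_KDA, MQ_RUP, MQ_CONTAMINANT, MQ_REVERSE, MQ_ONLY_SITE]
    _require_columns(raw, mandatory, path)

    line_ids = sample_sheet["line_id"].tolist()
    for line in line_ids:
        if MQ_INTENSITY_PREFIX + line not in raw.columns:
            raise SchemaError(f"{path}: missing mandatory column {MQ_INTENSITY_PREFIX + line!r}")

    df = pd.DataFrame(
        {
            "accessions": raw[MQ_ACCESSIONS].astype(str),
            "gene_name": raw[MQ_GENE].astype(str),
            "mw_da": pd.to_numeric(raw[MQ_MW_KDA], errors="raise") * 1000.0,
            "razor_unique_peptides": pd.to_numeric(raw[MQ_RUP], errors="raise").astype(int),
            "is_contaminant": raw[MQ_CONTAMINANT].astype(str).str.strip() == "+",
            "is_reverse": raw[MQ_REVERSE].astype(str).str.strip() == "+",
            "is_only_site": raw[MQ_ONLY_SITE].astype(str).str.strip() == "+",
        }
    )
    for line in line_ids:
        col = pd.to_numeric(raw[MQ_INTENSITY_PREFIX + line].replace("", np.nan), errors="raise")
        df[line] = col.astype(float)
    return validate_protein_groups(df, line_ids, source=path)


def validate_protein_groups(df: pd.DataFrame, line_ids, source="protein groups") -> pd.DataFrame:
    if len(df):
        if (df["mw_da"] <= 0).any():
            raise SchemaError(f"{source}: molecular weight must be positive")
        if (df["razor_unique_peptides"] < 0).any():
            raise SchemaError(f"{source}: negative Razor + unique peptides count")
        intens = df[list(line_ids)].to_numpy(dtype=float)
        if np.nanmin(intens, initial=0.0) < 0:
            raise SchemaError(f"{source}: negative reporter intensity")
    group_ids = df["accessions"].str.split(";").str[0]
    if group_ids.duplicated().any():
        dup = group_ids[group_ids.duplicated()].iloc[0]
        raise SchemaError(f"{source}: duplicate protein-group accession {dup!r}")
    df = df.set_index(pd.Index(group_ids, name="group_id"))
    df.attrs["table_kind"] = "protein_groups"
    df.attrs["line_ids"] = list(line_ids)
    return df


def protein_group_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """Protein x line reporter-intensity block of a protein-group table."""
    return table[table.attrs["line_ids"]]


# ---------------------------------------------------------------------------
# writers


def _to_tsv(df: pd.DataFrame, path, index: bool) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_table(table: pd.DataFrame, path) -> None:
    """Write any validated table back to TSV in its canonical on-disk layout."""
    kind = table.attrs.get("table_kind")
    if kind == "sample_sheet":
        _to_tsv(table[SAMPLE_SHEET_COLUMNS], path, index=False)
    elif kind == "allele_counts":
        _to_tsv(table[ALLELE_COUNT_COLUMNS], path, index=False)
    elif kind == "expression_matrix":
        _to_tsv(table, path, index=True)
    elif kind == "annotation":
        out = table.copy()
        for col in ANNOTATION_SET_COLUMNS:
            out[col] = out[col].astype(int)
        _to_tsv(out[ANNOTATION_COLUMNS], path, index=False)
    elif kind == "protein_groups":
        line_ids = table.attrs["line_ids"]
        out = pd.DataFrame(
            {
                MQ_ACCESSIONS: table["accessions"].to_numpy(),
                MQ_GENE: table["gene_name"].to_numpy(),
                MQ_MW_KDA: (table["mw_da"] / 1000.0).to_numpy(),
                MQ_RUP: table["razor_unique_peptides"].to_numpy(),
                MQ_CONTAMINANT: np.where(table["is_contaminant"], "+", ""),
                MQ_REVERSE: np.where(table["is_reverse"], "+", ""),
                MQ_ONLY_SITE: np.where(table["is_only_site"], "+", ""),
            }
        )
        for line in line_ids:
            out[MQ_INTENSITY_PREFIX + line] = table[line].to_numpy()
        _to_tsv(out, path, index=False)
    else:
        raise ValueError(f"cannot write table of unknown kind {kind!r}")
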