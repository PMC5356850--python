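"""Readers, writers and validation for the pipeline's file formats.

All tables are held as :class:`pandas.DataFrame` objects with fixed column
schemas. Genomic intervals are stored 0-based half-open (BED convention)
internally; user-facing labels are rendered 1-based inclusive as
``chrom:start–end`` (en dash), the notation used in methylation-array
literature for CpG islands.

Formats
-------
beta matrix      TSV, first column ``probe_id``, one column per sample,
                 values in [0, 1], missing cells empty or ``NA``.
probe manifest   TSV with columns probe_id, chrom, pos (1-based CpG site).
regions          BED4 with optional 5th (gene) and 6th (gene_context) columns.
sample sheet     TSV with columns patient_id, tumor_sample, normal_sample,
                 smoking_status (S or NS).
expression       TSV with columns gene, sample, context, rel_expr.
site methylation TSV with columns site_id, sample, percent_meth (0–100).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GENE_CONTEXTS",
    "EXPRESSION_CONTEXTS",
    "SMOKING_STATUSES",
    "region_label",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_regions_bed",
    "write_regions_bed",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_expression",
    "write_expression",
    "read_site_methylation",
    "write_site_methylation",
    "validate_design",
]

#: CpG-island position relative to its associated gene.
GENE_CONTEXTS = ("exon1", "gene_body", "upstream")

#: Compartments an expression measurement can come from.
EXPRESSION_CONTEXTS = (
    "tumor",            # tumor tissue of a matched case (sample = case id)
    "normal_pair",      # paired non-tumorous tissue (same case id)
    "cell_line",        # untreated cell line vs. normal reference
    "normal_reference", # commercial / pooled normal tissue
    "treated",          # demethylating-agent-treated cell line
    "vehicle",          # vehicle-treated control of the same line
)

SMOKING_STATUSES = ("S", "NS")

_FLOAT_FMT = "%.10g"
_BED_MISSING = "."


class ValidationError(ValueError):
    """A file or table violates the pipeline's structural contracts."""


def region_label(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval as 1-based inclusive ``chr:start–end``."""
    return f"{chrom}:{start + 1}–{end}"


# ---------------------------------------------------------------------------
# beta matrix


def read_beta_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probe × sample β-value matrix.

    Returns a float DataFrame indexed by probe_id with one column per sample;
    missing values are NaN. Duplicate probe ids and values outside [0, 1] are
    hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.name != "probe_id":
        raise ValidationError(
            f"{path}: first column must be 'probe_id', got {df.index.name!r}"
        )
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate probe ids: {list(dup[:5])}")
    out = df.apply(pd.to_numeric, errors="coerce")
    bad_parse = out.isna() & df.notna() & (df != "NA") & (df != "")
    if bad_parse.any().any():
        probe, sample = _first_true_cell(bad_parse)
        raise ValidationError(
            f"{path}: non-numeric β value at probe {probe!r}, sample {sample!r}"
        )
    out_of_range = (out < 0) | (out > 1)
    if out_of_range.any().any():
        probe, sample = _first_true_cell(out_of_range)
        raise ValidationError(
            f"{path}: β value outside [0, 1] at probe {probe!r}, sample "
            f"{sample!r} ({out.loc[probe, sample]})"
        )
    out.index = out.index.astype(str)
    out.index.name = "probe_id"
    out.columns = out.columns.astype(str)
    return out.astype(float)


def _first_true_cell(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    probe, sample = stacked[stacked].index[0]
    return str(probe), str(sample)


def write_beta_matrix(beta: pd.DataFrame, path: str | os.PathLike) -> None:
    beta = beta.copy()
    beta.index.name = "probe_id"
    beta.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# probe manifest

_MANIFEST_COLS = ["probe_id", "chrom", "pos"]


def read_probe_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    _require_columns(df, _MANIFEST_COLS, path)
    df = df[_MANIFEST_COLS].copy()
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate probe id {dup!r}")
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: probe positions must be ≥ 1 (1-based)")
    if (df["chrom"].str.len() == 0).any() or df["chrom"].isna().any():
        raise ValidationError(f"{path}: empty chromosome name in manifest")
    return df.reset_index(drop=True)


def write_probe_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    manifest[_MANIFEST_COLS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# regions (BED)

_REGION_COLS = ["region_id", "chrom", "start", "end", "gene", "gene_context"]


def read_regions_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read CpG-island regions from BED4(+2).

    Columns: chrom, start, end, name, and optionally gene symbol and gene
    context (one of exon1 / gene_body / upstream). Coordinates stay 0-based
    half-open; :func:`region_label` renders the 1-based inclusive display
    form. Missing name defaults to the display label.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"{chrom}:{start}-{end} (start must be < end)"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != _BED_MISSING else None
            gene = parts[4] if len(parts) > 4 and parts[4] != _BED_MISSING else None
            ctx = parts[5] if len(parts) > 5 and parts[5] != _BED_MISSING else None
            if ctx is not None and ctx not in GENE_CONTEXTS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown gene context {ctx!r} "
                    f"(expected one of {GENE_CONTEXTS})"
                )
            rows.append(
                {
                    "region_id": name if name is not None else region_label(chrom, start, end),
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "gene": gene,
                    "gene_context": ctx,
                }
            )
    df = pd.DataFrame(rows, columns=_REGION_COLS)
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate region id {dup!r}")
    return df


def write_regions_bed(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    out = regions[["chrom", "start", "end", "region_id", "gene", "gene_context"]].copy()
    out["gene"] = out["gene"].fillna(_BED_MISSING)
    out["gene_context"] = out["gene_context"].fillna(_BED_MISSING)
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# paired sample sheet

_SHEET_COLS = ["patient_id", "tumor_sample", "normal_sample", "smoking_status"]


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _SHEET_COLS, path)
    df = df[_SHEET_COLS].copy()
    bad_status = ~df["smoking_status"].isin(SMOKING_STATUSES)
    if bad_status.any():
        raise ValidationError(
            f"{path}: smoking_status must be one of {SMOKING_STATUSES}, got "
            f"{df.loc[bad_status, 'smoking_status'].iloc[0]!r}"
        )
    if df["patient_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate patient ids")
    if (df["tumor_sample"] == df["normal_sample"]).any():
        raise ValidationError(f"{path}: a pair references the same sample twice")
    all_samples = pd.concat([df["tumor_sample"], df["normal_sample"]])
    if all_samples.duplicated().any():
        dup = all_samples[all_samples.duplicated()].iloc[0]
        raise ValidationError(f"{path}: sample {dup!r} appears in more than one pair")
    return df.reset_index(drop=True)


def write_sample_sheet(design: pd.DataFrame, path: str | os.PathLike) -> None:
    design[_SHEET_COLS].to_csv(path, sep="\t", index=False)


def validate_design(design: pd.DataFrame, sample_ids: Iterable[str]) -> None:
    """Check that every sample referenced by the design exists in a matrix."""
    have = set(sample_ids)
    referenced = list(design["tumor_sample"]) + list(design["normal_sample"])
    orphans = sorted(s for s in referenced if s not in have)
    if orphans:
        raise ValidationError(f"design references missing samples: {orphans}")


# ---------------------------------------------------------------------------
# expression

_EXPR_COLS = ["gene", "sample", "context", "rel_expr"]


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str, "context": str})
    _require_columns(df, _EXPR_COLS, path)
    df = df[_EXPR_COLS].copy()
    bad_ctx = ~df["context"].isin(EXPRESSION_CONTEXTS)
    if bad_ctx.any():
        raise ValidationError(
            f"{path}: unknown expression context "
            f"{df.loc[bad_ctx, 'context'].iloc[0]!r}"
        )
    df["rel_expr"] = df["rel_expr"].astype(float)
    if (df["rel_expr"] < 0).any():
        raise ValidationError(f"{path}: negative relative expression value")
    if df.duplicated(subset=["gene", "sample", "context"]).any():
        key = df.loc[
            df.duplicated(subset=["gene", "sample", "context"]),
            ["gene", "sample", "context"],
        ].iloc[0]
        raise ValidationError(f"{path}: duplicate expression record {tuple(key)}")
    return df.reset_index(drop=True)


def write_expression(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr[_EXPR_COLS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# site-level percent methylation (pyrosequencing-style)

_SITE_COLS = ["site_id", "sample", "percent_meth"]


def read_site_methylation(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "sample": str})
    _require_columns(df, _SITE_COLS, path)
    df = df[_SITE_COLS].copy()
    df["percent_meth"] = df["percent_meth"].astype(float)
    bad = (df["percent_meth"] < 0) | (df["percent_meth"] > 100)
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(
            f"{path}: percent methylation outside [0, 100] at site "
            f"{row['site_id']!r}, sample {row['sample']!r} ({row['percent_meth']})"
        )
    return df.reset_index(drop=True)


def write_site_methylation(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    sites[_SITE_COLS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
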