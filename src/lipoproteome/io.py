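"""Tab-delimited readers and writers for every pipeline artifact.

All formats are plain TSV.  Missing intensity cells may be encoded as an
empty field or the literal ``NA``; both parse to the same mask.  Floats
are serialized with 17 significant digits so write-then-read round-trips
are exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lfq import IntensityMatrix
from .mr import SUMMARY_COLUMNS

__all__ = [
    "FormatError",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_summary_stats",
    "read_ld_matrix",
    "write_table",
    "read_table",
]

_NA_VALUES = ["", "NA"]
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Raised when an input file violates the declared TSV dialect."""


def _require_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def _check_unique(values: pd.Series, what: str, path: str | Path) -> None:
    dup = values[values.duplicated()]
    if not dup.empty:
        lines = [f"{v!r} (line {i + 2})" for i, v in dup.items()]
        raise FormatError(f"{path}: duplicated {what}: {', '.join(lines[:5])}")


def read_intensity_matrix(matrix_path: str | Path, samples_path: str | Path) -> IntensityMatrix:
    """Read a protein-intensity TSV plus its companion sample sheet.

    The matrix file has columns ``protein_id``, ``peptide_count``, then
    one column per sample; the sample sheet has ``sample_id``,
    ``condition``, ``pair_id``.
    """
    mat = pd.read_csv(matrix_path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype={"protein_id": str})
    _require_columns(mat, ["protein_id", "peptide_count"], matrix_path)
    _check_unique(mat["protein_id"].reset_index(drop=True), "protein_id", matrix_path)
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    _require_columns(sheet, ["sample_id", "condition", "pair_id"], samples_path)
    _check_unique(sheet["sample_id"].reset_index(drop=True), "sample_id", samples_path)
    sample_cols = [c for c in mat.columns if c not in ("protein_id", "peptide_count")]
    unknown = [s for s in sample_cols if s not in set(sheet["sample_id"])]
    if unknown:
        raise FormatError(f"{matrix_path}: samples missing from sample sheet: {unknown}")
    mat = mat.set_index("protein_id")
    intensities = mat[sample_cols].astype(float)
    bad = intensities.lt(0)
    if bad.any().any():
        prot = intensities.index[bad.any(axis=1)][0]
        raise FormatError(f"{matrix_path}: negative intensity for protein {prot!r}")
    sheet = sheet.set_index("sample_id").loc[sample_cols]
    return IntensityMatrix(
        intensities=intensities,
        condition=sheet["condition"],
        pair_id=sheet["pair_id"],
        peptide_counts=mat["peptide_count"].astype(int),
    )


def write_intensity_matrix(m: IntensityMatrix, matrix_path: str | Path, samples_path: str | Path) -> None:
    out = m.intensities.copy()
    out.insert(0, "peptide_count", m.peptide_counts)
    out.index.name = "protein_id"
    out.to_csv(matrix_path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)
    sheet = pd.DataFrame({"condition": m.condition, "pair_id": m.pair_id})
    sheet.index.name = "sample_id"
    sheet.to_csv(samples_path, sep="\t")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read GWAS summary statistics (``variant_id effect_allele
    other_allele beta se [pvalue] [eaf]``)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False,
                     dtype={"variant_id": str, "effect_allele": str, "other_allele": str})
    _require_columns(df, SUMMARY_COLUMNS, path)
    _check_unique(df["variant_id"].reset_index(drop=True), "variant_id", path)
    for col in ("beta", "se", "pvalue", "eaf"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if df["se"].le(0).any():
        row = int(df.index[df["se"].le(0)][0])
        raise FormatError(f"{path}: non-positive se at line {row + 2}")
    return df


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square LD (r^2) matrix keyed by variant id on both axes."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    if list(ld.index) != list(ld.columns):
        raise FormatError(f"{path}: LD matrix row and column ids differ")
    vals = ld.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise FormatError(f"{path}: LD entries must lie in [0, 1]")
    return ld


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Serialize any result table with round-trip-exact floats."""
    df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT, index=index)


def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, index_col=index_col)
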