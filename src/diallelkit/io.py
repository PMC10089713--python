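"""Reading and writing of diallel tables, panels and genotypes.

All on-disk formats are plain text: tab-separated tables with a header
for vial records, panels and genotypes, JSON for ground-truth and fit
reports.  Genotypes can also be imported from an uncompressed VCF with
one sample per inbred line; any non-homozygous genotype call is treated
as missing, matching the quality control applied to inbred panels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datatypes import DIALLEL_COLUMNS, DiallelDataset, GenotypeMatrix, LinePanel

__all__ = [
    "write_dataset", "read_dataset",
    "write_panel", "read_panel",
    "write_genotypes", "read_genotypes", "read_genotypes_vcf",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def write_dataset(dataset: DiallelDataset, path: PathLike) -> None:
    cols = list(DIALLEL_COLUMNS)
    if "total_adjusted" in dataset.df.columns:
        cols = cols + ["total_adjusted"]
    dataset.df[cols].to_csv(path, sep="\t", index=False)


def read_dataset(path: PathLike) -> DiallelDataset:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"female_line": str,
                                                "male_line": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = [c for c in DIALLEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}, line 1: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        for col in ("n_female", "n_male"):
            val = getattr(row, col)
            if not float(val).is_integer() or val < 0:
                raise ParseError(
                    f"{path}, line {i}: {col}={val!r} is not a "
                    "non-negative integer")
    return DiallelDataset(df)


def write_panel(panel: LinePanel, path: PathLike) -> None:
    df = pd.DataFrame({"line_id": panel.line_ids, "infected": panel.infected})
    if panel.expression is not None:
        df["expression"] = panel.expression.values
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel(path: PathLike) -> LinePanel:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    for col in ("line_id", "infected"):
        if col not in df.columns:
            raise ParseError(f"{path}, line 1: missing column {col!r}")
    bad = df.index[~df["infected"].isin((0, 1))]
    if len(bad):
        raise ParseError(f"{path}, line {bad[0] + 2}: infected must be 0/1")
    expr = df["expression"].values if "expression" in df.columns else None
    return LinePanel(line_ids=df["line_id"].tolist(),
                     infected=df["infected"].to_numpy(int),
                     expression=expr)


def write_genotypes(genotypes: GenotypeMatrix, path: PathLike) -> None:
    out = genotypes.calls.copy()
    out.index.name = "line_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_genotypes(path: PathLike) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col="line_id",
                         na_values=["NA"], dtype=str)
    except (pd.errors.EmptyDataError, ValueError) as exc:
        raise ParseError(f"{path}: not a genotype table ({exc})") from exc
    df.index = df.index.astype(str)
    mat = df.apply(pd.to_numeric, errors="coerce")
    # anything that was neither 0/1/NA in the input is a hard error
    bad = mat.isna() & df.notna()
    if bad.values.any():
        r, c = np.argwhere(bad.values)[0]
        raise ParseError(
            f"{path}, line {r + 2}: unknown genotype code "
            f"{df.iat[r, c]!r} for variant {df.columns[c]!r}")
    invalid = ~(mat.isna() | (mat == 0) | (mat == 1))
    if invalid.values.any():
        r, c = np.argwhere(invalid.values)[0]
        raise ParseError(
            f"{path}, line {r + 2}: genotype {mat.iat[r, c]!r} is not 0/1/NA")
    return GenotypeMatrix(calls=mat)


def read_genotypes_vcf(path: PathLike,
                       lines: Optional[list[str]] = None) -> GenotypeMatrix:
    """Import a genotype matrix from a VCF with one sample per line.

    Homozygous reference calls become 0, homozygous alternate calls 1;
    heterozygous or uncalled genotypes are missing (segregating calls
    within an inbred line are removed).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    names, columns, positions = [], [], []
    for var in vcf:
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.where(gt == 0, 0.0, np.where(gt == 3, 1.0, np.nan))
        vid = var.ID if var.ID not in (None, ".") else \
            f"{var.CHROM}_{var.POS}_{var.REF}_{var.ALT[0] if var.ALT else '.'}"
        names.append(vid)
        columns.append(col)
        positions.append(var.POS)
    if not names:
        raise ParseError(f"{path}: VCF contains no variants")
    calls = pd.DataFrame(np.column_stack(columns), index=samples, columns=names)
    if lines is not None:
        calls = calls.loc[lines]
    return GenotypeMatrix(calls=calls,
                          positions=pd.Series(positions, index=names))
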