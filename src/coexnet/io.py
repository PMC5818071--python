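"""TSV readers/writers for the pipeline's tabular formats."""

from __future__ import annotations

import os

import pandas as pd

__all__ = ["read_expression", "read_samples", "read_probe_map", "read_ct_table", "read_truth"]


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.index.name = "gene_id"
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if expr.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return expr


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "timepoint"):
        if col not in samples.columns:
            raise ValueError(f"sample table {path} lacks required column {col!r}")
        if samples[col].isna().any():
            raise ValueError(f"sample table {path} has missing values in {col!r}")
    return samples


def read_probe_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV (probe id, gene id) -> mapping."""
    table = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"probe map {path} must have two columns")
    first = table.iloc[0]
    if {str(first[0]).lower(), str(first[1]).lower()} & {"probe", "probe_id", "gene", "gene_id"}:
        table = table.iloc[1:]
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Long-format qPCR table: sample_id, group, gene, ct."""
    ct = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group", "gene", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table {path} lacks required column {col!r}")
    return ct


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
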