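"""Tab-separated text I/O for every pipeline table.

All tables are written with a header row and the row name in the first
column, using a fixed float format so repeated writes of identical data
are byte-stable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .deconvolve import ReferenceMatrix

__all__ = [
    "write_table", "read_beta", "write_beta", "read_pheno", "write_pheno",
    "read_fractions", "write_fractions", "read_truth", "write_truth",
    "read_reference", "write_reference", "read_dmc_table", "write_dmc_table",
]

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index_label=index_label or df.index.name)


def _read(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_beta(beta: pd.DataFrame, path) -> None:
    write_table(beta, path, index_label="cpg_id")


def read_beta(path) -> pd.DataFrame:
    df = _read(path)
    df.index.name = "cpg_id"
    return df


def write_pheno(pheno: pd.DataFrame, path) -> None:
    write_table(pheno, path, index_label="sample_id")


def read_pheno(path) -> pd.DataFrame:
    df = _read(path)
    df.index.name = "sample_id"
    return df


def write_fractions(fractions: pd.DataFrame, path) -> None:
    write_table(fractions, path, index_label="sample_id")


def read_fractions(path) -> pd.DataFrame:
    df = _read(path)
    df.index.name = "sample_id"
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_reference(ref: ReferenceMatrix, path) -> None:
    combined = ref.values.copy()
    combined["marker_for"] = ref.marker_for
    combined["direction"] = ref.direction
    write_table(combined, path, index_label="cpg_id")


def read_reference(path) -> ReferenceMatrix:
    df = _read(path)
    df.index.name = "cpg_id"
    meta = ["marker_for", "direction"]
    return ReferenceMatrix(
        values=df.drop(columns=meta),
        marker_for=df["marker_for"],
        direction=df["direction"],
    )


def write_dmc_table(table: pd.DataFrame, path) -> None:
    write_table(table, path, index_label="cpg_id")


def read_dmc_table(path) -> pd.DataFrame:
    df = _read(path)
    df.index.name = "cpg_id"
    return df
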