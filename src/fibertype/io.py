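"""Reading and writing the pipeline's plain-text table dialects.

The canonical exchange format is a long-format TSV with one row per
(sample, peptide) observation:

    sample_id <TAB> protein_group <TAB> peptide_sequence <TAB> proteotypic <TAB> intensity

Header required, UTF-8, '.' decimal separator.  Missing intensity is an
empty field (or "NA") on read and an empty field on write — never zero.
Proteotypicity is TRUE/FALSE, parsed case-insensitively.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import PeptideMatrix

log = logging.getLogger(__name__)

LONG_COLUMNS = [
    "sample_id",
    "protein_group",
    "peptide_sequence",
    "proteotypic",
    "intensity",
]

_TRUE = {"true"}
_FALSE = {"false"}
_MISSING = {"", "na", "nan"}


def read_long_table(path: str | Path) -> PeptideMatrix:
    """Parse a long-format peptide TSV into a :class:`PeptideMatrix`.

    Absent (sample, peptide) pairs become missing cells.  Duplicate
    (sample, peptide) keys, negative intensities and unparseable
    proteotypicity flags raise with the offending line number (1-based,
    counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")

    lines = df.index + 2  # header is line 1

    dup = df.duplicated(subset=["sample_id", "peptide_sequence"], keep=False)
    if dup.any():
        first = int(lines[dup.to_numpy()][0])
        key = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (sample, peptide) key "
            f"({key['sample_id']}, {key['peptide_sequence']}) at line {first}"
        )

    flags = df["proteotypic"].str.strip().str.lower()
    bad_flag = ~flags.isin(_TRUE | _FALSE)
    if bad_flag.any():
        i = int(np.flatnonzero(bad_flag.to_numpy())[0])
        raise ValueError(
            f"{path}: unknown proteotypicity flag "
            f"{df['proteotypic'].iloc[i]!r} at line {int(lines[i])}"
        )

    raw = df["intensity"].str.strip()
    is_missing = raw.str.lower().isin(_MISSING)
    values = pd.to_numeric(raw.where(~is_missing), errors="coerce")
    unparseable = values.isna() & ~is_missing
    if unparseable.any():
        i = int(np.flatnonzero(unparseable.to_numpy())[0])
        raise ValueError(
            f"{path}: unparseable intensity {raw.iloc[i]!r} at line {int(lines[i])}"
        )
    negative = values < 0
    if negative.any():
        i = int(np.flatnonzero(negative.to_numpy())[0])
        raise ValueError(
            f"{path}: negative intensity {raw.iloc[i]!r} at line {int(lines[i])}"
        )

    # one protein group and one flag per peptide
    per_pep = df.drop_duplicates("peptide_sequence").set_index("peptide_sequence")
    conflicting = df.groupby("peptide_sequence")["protein_group"].nunique()
    if (conflicting > 1).any():
        pep = conflicting.index[conflicting > 1][0]
        raise ValueError(f"{path}: peptide {pep!r} maps to multiple protein groups")

    wide = (
        df.assign(value=values)
        .pivot(index="peptide_sequence", columns="sample_id", values="value")
    )
    wide.index.name = None
    wide.columns.name = None
    return PeptideMatrix(
        intensities=wide,
        peptide_to_protein=per_pep["protein_group"].rename("protein"),
        proteotypic=flags.groupby(df["peptide_sequence"]).first().isin(_TRUE)
        .rename("proteotypic"),
    )


def write_long_table(matrix: PeptideMatrix, path: str | Path) -> None:
    """Write a matrix in the long TSV dialect (missing cells -> empty field)."""
    path = Path(path)
    rows = []
    for pep in matrix.peptides:
        prot = matrix.peptide_to_protein.loc[pep]
        flag = "TRUE" if bool(matrix.proteotypic.loc[pep]) else "FALSE"
        for s in matrix.samples:
            v = matrix.intensities.at[pep, s]
            rows.append(
                (s, prot, pep, flag, "" if pd.isna(v) else repr(float(v)))
            )
    out = pd.DataFrame(rows, columns=LONG_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.Series:
    """Sample -> fiber-type label table (TSV: sample_id TAB fiber_type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, fiber_type)")
    return df.set_index(df.columns[0])[df.columns[1]].rename("fiber_type")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("fiber_type").rename_axis("sample_id").to_csv(path, sep="\t")


def read_annotation_map(path: str | Path) -> pd.Series:
    """Protein -> annotation-category map (TSV: accession TAB category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (accession, category)")
    return df.set_index(df.columns[0])[df.columns[1]].rename("category")


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "protein") -> None:
    """Protein x sample TSV with a one-line header; missing -> empty field."""
    df.rename_axis(index_name).to_csv(path, sep="\t", na_rep="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df
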