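"""Absolute label-free protein quantification.

The chain implemented here converts a raw peptide intensity matrix into
per-sample absolute protein amounts:

1. **LOESS normalization** — intensity-dependent between-sample biases are
   removed by locally weighted regression of per-sample log2 differences
   against the per-peptide mean (cyclic MA-style normalization against the
   row-mean reference).
2. **iBAQ** — for each protein and sample, the sum of its observed peptide
   intensities divided by the number of theoretically observable tryptic
   peptides of that protein.
3. **aLFQ scaling** — iBAQ values are converted to absolute amounts by
   proportional allocation of a known total protein mass (default 200 ng),
   performed separately per sample so every sample carries exactly the
   configured total.
4. **Percentages** — per-sample relative shares summing to 100%.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import PeptideMatrix

log = logging.getLogger(__name__)

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
_TRYPTIC_SPLIT = re.compile(r"(?<=[KR])(?!P)")

DEFAULT_TOTAL_NG = 200.0


@dataclass
class ProteinQuant:
    """Protein x sample quantification result.

    ``quantity_ng`` sums to ``total_ng`` within each sample over non-missing
    proteins; ``percent`` sums to 100.
    """

    ibaq: pd.DataFrame
    quantity_ng: pd.DataFrame
    percent: pd.DataFrame
    total_ng: float
    sample_labels: pd.Series | None = None


# ---------------------------------------------------------------------------
# LOESS normalization
# ---------------------------------------------------------------------------

def loess_normalize(
    matrix: PeptideMatrix,
    span: float = 0.7,
    iterations: int = 3,
    min_shared: int = 10,
) -> PeptideMatrix:
    """Remove intensity-dependent between-sample bias on the log2 scale.

    Each cycle recomputes the per-peptide row mean of log2 intensities as
    the reference, then for every sample fits ``lowess`` of
    M = sample - reference against A = (sample + reference)/2 over the
    peptides observed in both, and subtracts the fitted trend from the
    sample.  Missing cells are ignored throughout and remain missing.
    Returns intensities on the original linear scale.
    """
    if matrix.intensities.shape[1] < 2:
        raise ValueError("LOESS normalization requires at least 2 samples")
    x = matrix.log2()
    for _ in range(iterations):
        ref = x.mean(axis=1)
        for s in x.columns:
            shared = x[s].notna() & ref.notna()
            n = int(shared.sum())
            if n < min_shared:
                raise ValueError(
                    f"sample {s!r} shares only {n} non-missing peptides "
                    f"with the reference (need >= {min_shared})"
                )
            a = ((x.loc[shared, s] + ref[shared]) / 2.0).to_numpy()
            m = (x.loc[shared, s] - ref[shared]).to_numpy()
            fit = lowess(m, a, frac=span, return_sorted=False)
            x.loc[shared, s] = x.loc[shared, s] - fit
    return matrix.with_intensities(np.exp2(x))


# ---------------------------------------------------------------------------
# Theoretical tryptic peptide counts
# ---------------------------------------------------------------------------

def digest_tryptic(sequence: str) -> list[str]:
    """Fully tryptic fragments: cleave C-terminal of K/R, not before P."""
    if not sequence:
        return []
    return [f for f in _TRYPTIC_SPLIT.split(sequence) if f]


def theoretical_peptide_count(
    sequence: str, min_len: int = 6, max_len: int = 30
) -> int:
    """Number of fully tryptic peptides with length in [min_len, max_len].

    Zero missed cleavages.  An empty sequence yields 0 with a warning;
    characters outside the 20-letter amino-acid alphabet raise.
    """
    if not sequence:
        warnings.warn("empty protein sequence: theoretical peptide count is 0")
        return 0
    bad = set(sequence.upper()) - _VALID_AA
    if bad:
        raise ValueError(f"illegal amino-acid characters: {sorted(bad)}")
    return sum(
        1 for f in digest_tryptic(sequence.upper()) if min_len <= len(f) <= max_len
    )


def counts_from_fasta(
    path, min_len: int = 6, max_len: int = 30
) -> dict[str, int]:
    """Theoretical peptide counts per accession from a protein FASTA.

    The accession is the first whitespace-delimited token of each header.
    """
    from Bio import SeqIO

    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        counts[rec.id] = theoretical_peptide_count(str(rec.seq), min_len, max_len)
    return counts


def observed_peptide_counts(matrix: PeptideMatrix) -> dict[str, int]:
    """Fallback for missing FASTA: distinct observed peptides per protein.

    This approximates the theoretical count by the data set's own coverage
    and is logged as such.
    """
    log.info(
        "no FASTA provided: using distinct observed peptides per protein "
        "as an approximation of theoretical peptide counts"
    )
    mapping = matrix.peptide_to_protein.loc[matrix.intensities.index]
    return mapping.groupby(mapping).size().to_dict()


# ---------------------------------------------------------------------------
# iBAQ / aLFQ / percentages
# ---------------------------------------------------------------------------

def ibaq(
    matrix: PeptideMatrix, theoretical_counts: dict[str, int] | pd.Series
) -> pd.DataFrame:
    """iBAQ per protein and sample.

    iBAQ(p, s) = sum of non-missing peptide intensities of protein p in
    sample s, divided by the theoretical peptide count of p.  A protein with
    zero observed peptides in a sample is missing there (never zero).
    """
    counts = pd.Series(theoretical_counts, dtype=float)
    if (counts <= 0).any():
        bad = counts.index[counts <= 0].tolist()
        raise ValueError(f"theoretical peptide counts must be positive: {bad}")
    mapping = matrix.peptide_to_protein.loc[matrix.intensities.index]
    sums = matrix.intensities.groupby(mapping).sum(min_count=1)
    missing = sums.index.difference(counts.index)
    if len(missing):
        raise ValueError(
            f"no theoretical peptide count for proteins: {list(missing[:5])}"
        )
    return sums.div(counts.loc[sums.index], axis=0)


def alfq_scale(
    ibaq_values: pd.DataFrame,
    total_ng: float = DEFAULT_TOTAL_NG,
    per_sample: bool = True,
) -> pd.DataFrame:
    """Allocate a known total protein amount proportionally to iBAQ.

    With ``per_sample`` (the default) each sample is scaled separately so
    its non-missing quantities sum exactly to ``total_ng``.  With
    ``per_sample=False`` the classical global variant divides by the grand
    sum over all samples, so only the grand total — not each sample — equals
    ``total_ng``.
    """
    if total_ng <= 0:
        raise ValueError("total_ng must be positive")
    if per_sample:
        col_sums = ibaq_values.sum(axis=0, min_count=1)
        empty = col_sums.index[col_sums.isna() | (col_sums <= 0)]
        if len(empty):
            raise ValueError(f"sample(s) with no quantifiable protein: {list(empty)}")
        return ibaq_values.div(col_sums, axis=1) * total_ng
    grand = float(np.nansum(ibaq_values.to_numpy()))
    if grand <= 0:
        raise ValueError("no quantifiable protein in the whole data set")
    return ibaq_values / grand * total_ng


def percentage(quantity_ng: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative shares in percent (each sample sums to 100)."""
    col_sums = quantity_ng.sum(axis=0, min_count=1)
    bad = col_sums.index[col_sums.isna() | (col_sums <= 0)]
    if len(bad):
        raise ValueError(f"sample(s) with non-positive total: {list(bad)}")
    return quantity_ng.div(col_sums, axis=1) * 100.0


def quantify(
    matrix: PeptideMatrix,
    theoretical_counts: dict[str, int] | None = None,
    total_ng: float = DEFAULT_TOTAL_NG,
    span: float = 0.7,
    iterations: int = 3,
    normalize: bool = True,
    per_sample: bool = True,
) -> ProteinQuant:
    """End-to-end quantification: LOESS -> iBAQ -> aLFQ -> percentages."""
    m = loess_normalize(matrix, span=span, iterations=iterations) if normalize else matrix
    counts = theoretical_counts or observed_peptide_counts(m)
    ib = ibaq(m, counts)
    ng = alfq_scale(ib, total_ng=total_ng, per_sample=per_sample)
    pct = percentage(ng)
    return ProteinQuant(
        ibaq=ib,
        quantity_ng=ng,
        percent=pct,
        total_ng=total_ng,
        sample_labels=matrix.sample_labels,
    )
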