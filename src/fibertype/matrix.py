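"""Core in-memory container for peptide-level quantitative data.

A :class:`PeptideMatrix` holds a peptide x sample intensity table together
with the peptide -> protein-group mapping, per-peptide proteotypicity flags
and (optionally) per-sample fiber-type labels.  Intensities are linear-scale
positive reals; missing observations are ``NaN``, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FIBER_TYPES = ("I", "IIa", "IIb", "IIx")


@dataclass
class PeptideMatrix:
    """Peptide x sample intensity matrix with peptide/sample metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by peptide sequence, columns are sample ids.
        Values are linear-scale intensities (>= 0) with ``NaN`` for missing.
    peptide_to_protein
        Series mapping each peptide sequence to exactly one protein-group
        accession.
    proteotypic
        Boolean Series: whether the peptide is unique to its protein group.
    sample_labels
        Optional Series mapping sample id -> fiber type.
    """

    intensities: pd.DataFrame
    peptide_to_protein: pd.Series
    proteotypic: pd.Series
    sample_labels: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            raise ValueError("duplicate peptide sequences in intensity matrix")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        missing_map = idx.difference(self.peptide_to_protein.index)
        if len(missing_map):
            raise ValueError(
                f"peptides without protein mapping: {list(missing_map[:5])}"
            )
        missing_flag = idx.difference(self.proteotypic.index)
        if len(missing_flag):
            raise ValueError(
                f"peptides without proteotypicity flag: {list(missing_flag[:5])}"
            )
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("negative intensities are not allowed")
        if self.sample_labels is not None:
            missing_lab = self.intensities.columns.difference(self.sample_labels.index)
            if len(missing_lab):
                raise ValueError(f"samples without label: {list(missing_lab[:5])}")
            # align to column order for downstream group-bys
            self.sample_labels = self.sample_labels.loc[self.intensities.columns]

    # -- convenience views -------------------------------------------------

    @property
    def peptides(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def log2(self) -> pd.DataFrame:
        """log2-transformed intensities (missing stays NaN)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.intensities)

    def with_intensities(self, intensities: pd.DataFrame) -> "PeptideMatrix":
        """Copy of this matrix with a replaced intensity table."""
        return PeptideMatrix(
            intensities=intensities,
            peptide_to_protein=self.peptide_to_protein.loc[intensities.index],
            proteotypic=self.proteotypic.loc[intensities.index],
            sample_labels=self.sample_labels,
        )

    def protein_of(self, peptide: str) -> str:
        return str(self.peptide_to_protein.loc[peptide])
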