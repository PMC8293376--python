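"""Synthetic fiber-type peptide data with known ground truth.

The generator emulates the statistical structure of a DIA peptide export
from laser-microdissected muscle fibers of the four murine fiber types
(I, IIa, IIb, IIx):

* four MYH-like isoform proteins whose expected intensity is maximal in
  their characteristic fiber type (MYH7->I, MYH2->IIa, MYH4->IIb,
  MYH1->IIx) with coarse cross-contamination between types,
* slow and fast sarcomeric marker proteins with monotone abundance
  gradients across the I -> IIa -> IIx -> IIb ordering,
* a background of proteins without any fiber-type effect,
* log-normal intensities (Normal on the log2 scale), and
* left-censored missingness: the lower a cell's latent log2 intensity,
  the higher its probability of being unobserved.

Optionally two panel peptides are planted that jointly, but neither
alone, distinguish all four fiber types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix import FIBER_TYPES, PeptideMatrix

# Fixed names for the two planted panel peptides.  Peptide A separates the
# three fast types from each other; peptide B separates type I from the rest.
PANEL_PEPTIDE_A = "TINEVENQVLTR"
PANEL_PEPTIDE_B = "IAEQELLDASER"
PANEL_PROTEIN_A = "ACTN3_SYN"
PANEL_PROTEIN_B = "MYH1P_SYN"

# Coarse linear-scale cross-contamination profiles of the four MYH-like
# isoforms over (I, IIa, IIb, IIx): each isoform peaks in its characteristic
# type, with qualitative carry-over between physiologically adjacent types
# (e.g. the type-I isoform also present at ~20% level in IIa, near-zero in
# IIb).  Only this qualitative structure is asserted downstream.
MYH_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "MYH7_SYN": (1.00, 0.20, 0.001, 0.002),
    "MYH2_SYN": (0.44, 1.00, 0.040, 0.070),
    "MYH4_SYN": (0.015, 0.020, 1.00, 0.220),
    "MYH1_SYN": (0.11, 0.17, 0.210, 1.00),
}
MYH_CHARACTERISTIC_TYPE = {
    "MYH7_SYN": "I",
    "MYH2_SYN": "IIa",
    "MYH4_SYN": "IIb",
    "MYH1_SYN": "IIx",
}

# log2 fiber-type effects for marker proteins, over (I, IIa, IIb, IIx).
# Slow markers fall monotonically along I > IIa > IIx > IIb, fast markers
# rise along the same ordering.
_SLOW_EFFECT = {"I": 2.0, "IIa": 1.0, "IIx": -1.0, "IIb": -2.0}
_FAST_EFFECT = {"I": -2.0, "IIa": -1.0, "IIx": 1.0, "IIb": 2.0}
N_SLOW_MARKERS = 5
N_FAST_MARKERS = 5

_AA_POOL = list("ACDEFGHILMNQSTVWY")  # no K/R/P: cleavage-neutral interior


@dataclass
class SimConfig:
    """Configuration of the synthetic fiber-type data set.

    Defaults mirror the study design the pipeline targets: 4 fiber types x
    14 samples (56 in total) and on the order of a thousand quantified
    peptides, with ~20% left-censored missing cells.
    """

    n_samples_per_type: int = 14
    n_background_proteins: int = 250
    peptides_per_protein: tuple[int, int] = (2, 8)
    log2_mean_range: tuple[float, float] = (18.0, 30.0)
    within_type_sd: float = 0.4
    missing_fraction: float = 0.2
    censoring_strength: float = 1.0
    plant_panel: bool = False
    panel_separation: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_type < 1:
            raise ValueError("n_samples_per_type must be a positive integer")
        if self.n_background_proteins < 1:
            raise ValueError("n_background_proteins must be a positive integer")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be a non-degenerate range")
        a, b = self.log2_mean_range
        if not a < b:
            raise ValueError("log2_mean_range must be a non-degenerate interval")
        if self.within_type_sd <= 0:
            raise ValueError("within_type_sd must be positive")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must lie in [0, 1]")
        if self.censoring_strength <= 0:
            raise ValueError("censoring_strength must be positive")
        if self.panel_separation <= 0:
            raise ValueError("panel_separation must be positive")


@dataclass
class GroundTruth:
    """What the generator knows about the data it emitted."""

    planted_panel_peptides: list[str]
    fiber_type_of_sample: pd.Series
    true_protein_class: dict[str, str]  # MYH-like / slow-marker / fast-marker / background
    latent_log2: pd.DataFrame | None = field(default=None, repr=False)
    """Pre-censoring log2 intensity matrix (for diagnostics and tests)."""


def _random_peptide(rng: np.random.Generator, taken: set[str]) -> str:
    """A unique tryptic-looking sequence: K/R-terminated, no interior K/R/P."""
    while True:
        n = int(rng.integers(7, 15))
        body = "".join(rng.choice(_AA_POOL, size=n - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in taken:
            taken.add(pep)
            return pep


def generate(config: SimConfig) -> tuple[PeptideMatrix, GroundTruth]:
    """Draw one synthetic data set.

    Returns the (censored) peptide matrix plus ground truth; the ground
    truth carries the pre-censoring latent log2 matrix so the left-censoring
    mechanism can be audited.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = [
        f"{t}_{i + 1:02d}"
        for t in FIBER_TYPES
        for i in range(config.n_samples_per_type)
    ]
    labels = pd.Series(
        [s.rsplit("_", 1)[0] for s in samples], index=samples, name="fiber_type"
    )

    proteins: list[tuple[str, str]] = []  # (accession, class)
    proteins += [(acc, "MYH-like") for acc in MYH_PROFILES]
    proteins += [(f"SLOW{i + 1}_SYN", "slow-marker") for i in range(N_SLOW_MARKERS)]
    proteins += [(f"FAST{i + 1}_SYN", "fast-marker") for i in range(N_FAST_MARKERS)]
    proteins += [
        (f"BG{i + 1:04d}_SYN", "background")
        for i in range(config.n_background_proteins)
    ]

    lo, hi = config.peptides_per_protein
    taken: set[str] = {PANEL_PEPTIDE_A, PANEL_PEPTIDE_B}
    pep_rows: list[tuple[str, str, float]] = []  # (peptide, protein, ionization offset)
    for acc, _cls in proteins:
        n_pep = int(rng.integers(lo, hi + 1))
        for _ in range(n_pep):
            pep_rows.append((_random_peptide(rng, taken), acc, rng.normal(0.0, 1.0)))

    peptides = [p for p, _, _ in pep_rows]
    pep_protein = pd.Series({p: acc for p, acc, _ in pep_rows}, name="protein")
    # every generator peptide is unique to its protein by construction
    proteotypic = pd.Series(True, index=pd.Index(peptides), name="proteotypic")

    base = {acc: rng.uniform(*config.log2_mean_range) for acc, _ in proteins}
    cls_of = dict(proteins)

    def type_effect(acc: str, fiber: str) -> float:
        cls = cls_of[acc]
        if cls == "MYH-like":
            prof = dict(zip(FIBER_TYPES, MYH_PROFILES[acc]))
            return math.log2(prof[fiber])
        if cls == "slow-marker":
            return _SLOW_EFFECT[fiber]
        if cls == "fast-marker":
            return _FAST_EFFECT[fiber]
        return 0.0

    mean = np.empty((len(peptides), len(samples)))
    for j, s in enumerate(samples):
        fiber = labels.loc[s]
        for i, (pep, acc, ion) in enumerate(pep_rows):
            mean[i, j] = base[acc] + ion + type_effect(acc, fiber)
    latent = mean + rng.normal(0.0, config.within_type_sd, size=mean.shape)
    latent_df = pd.DataFrame(latent, index=pd.Index(peptides), columns=samples)

    censored = latent_df.copy()
    if config.missing_fraction > 0:
        mask = _censor_mask(
            latent, config.missing_fraction, config.censoring_strength, rng
        )
        censored = censored.mask(pd.DataFrame(mask, index=censored.index,
                                              columns=censored.columns))

    matrix = PeptideMatrix(
        intensities=np.exp2(censored),
        peptide_to_protein=pep_protein,
        proteotypic=proteotypic,
        sample_labels=labels,
    )

    planted: list[str] = []
    if config.plant_panel:
        matrix = plant_panel(
            matrix,
            separation=config.panel_separation,
            seed=int(rng.integers(2**31)),
            sd=config.within_type_sd,
        )
        planted = [PANEL_PEPTIDE_A, PANEL_PEPTIDE_B]

    truth = GroundTruth(
        planted_panel_peptides=planted,
        fiber_type_of_sample=labels,
        true_protein_class=cls_of,
        latent_log2=latent_df,
    )
    return matrix, truth


def _censor_mask(
    latent: np.ndarray,
    missing_fraction: float,
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Left-censoring indicator: P(missing) = Phi((c - x) * strength / sd).

    The threshold c is solved by bisection so that the expected overall
    missing fraction equals ``missing_fraction``.
    """
    if missing_fraction >= 1.0:
        return np.ones_like(latent, dtype=bool)
    sd = float(latent.std())
    scale = sd / strength

    def expected(c: float) -> float:
        return float(norm.cdf((c - latent) / scale).mean())

    lo, hi = latent.min() - 10 * sd, latent.max() + 10 * sd
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < missing_fraction:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    prob = norm.cdf((c - latent) / scale)
    return rng.random(latent.shape) < prob


def plant_panel(
    matrix: PeptideMatrix,
    separation: float,
    seed: int,
    sd: float = 0.4,
    base_log2: float = 24.0,
) -> PeptideMatrix:
    """Add the two-peptide discriminative panel to an existing matrix.

    Peptide A (``TINEVENQVLTR``) takes three distinct levels across
    IIa < IIb < IIx (type I sits at the IIa level), peptide B
    (``IAEQELLDASER``) lifts all fast types ``separation`` log2 units above
    type I.  Jointly — but neither alone — the pair distinguishes all four
    types.  Planted peptides are fully observed (no censoring).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    labels = matrix.sample_labels
    if labels is None or labels.nunique() < 2:
        raise ValueError("plant_panel requires sample labels with >= 2 classes")
    rng = np.random.default_rng(seed)

    level_a = {"I": 0.0, "IIa": 0.0, "IIb": separation, "IIx": 2 * separation}
    level_b = {"I": 0.0, "IIa": separation, "IIb": separation, "IIx": separation}

    def draw(levels: dict[str, float]) -> np.ndarray:
        mu = np.array([base_log2 + levels.get(str(labels.loc[s]), 0.0)
                       for s in matrix.samples])
        return np.exp2(mu + rng.normal(0.0, sd, size=len(mu)))

    new_rows = pd.DataFrame(
        [draw(level_a), draw(level_b)],
        index=pd.Index([PANEL_PEPTIDE_A, PANEL_PEPTIDE_B]),
        columns=matrix.samples,
    )
    intensities = pd.concat([matrix.intensities, new_rows])
    pep_protein = pd.concat(
        [
            matrix.peptide_to_protein,
            pd.Series({PANEL_PEPTIDE_A: PANEL_PROTEIN_A,
                       PANEL_PEPTIDE_B: PANEL_PROTEIN_B}),
        ]
    )
    proteotypic = pd.concat(
        [matrix.proteotypic,
         pd.Series({PANEL_PEPTIDE_A: True, PANEL_PEPTIDE_B: True})]
    )
    return PeptideMatrix(intensities, pep_protein, proteotypic, labels)
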