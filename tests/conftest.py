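import numpy as np
import pandas as pd
import pytest

from fibertype import PeptideMatrix, SimConfig, generate


def make_matrix(values: dict, protein_of: dict, proteotypic=None, labels=None):
    """Build a PeptideMatrix from {peptide: {sample: intensity}}."""
    df = pd.DataFrame(values).T.astype(float)
    prot = pd.Series(protein_of)
    flags = pd.Series(
        True if proteotypic is None else proteotypic, index=df.index, dtype=bool
    )
    lab = pd.Series(labels) if labels is not None else None
    return PeptideMatrix(df, prot, flags, lab)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic data set shared across tests."""
    cfg = SimConfig(
        n_samples_per_type=6, n_background_proteins=40, seed=11, plant_panel=True
    )
    matrix, truth = generate(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
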