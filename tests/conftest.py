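import numpy as np
import pandas as pd
import pytest

from covquant import PeptideTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_table():
    """3 peptides x 4 samples with one missing value and a protein column."""
    df = pd.DataFrame(
        {
            "S1": [4.0, 8.0, 2.0],
            "S2": [2.0, 4.0, np.nan],
            "S3": [1.0, 2.0, 0.5],
            "S4": [8.0, 16.0, 4.0],
        },
        index=["PEPA", "PEPB", "PEPC"],
    )
    proteins = pd.Series(["prot1", "prot1", "prot2"], index=df.index)
    return PeptideTable(df, scale="raw", proteins=proteins)


def coherent_group(rng, n_peptides=4, n_samples=20, noise_sd=0.2, loadings=None):
    """Peptide log-ratio rows sharing one latent signal (x = lambda z + eps)."""
    z = rng.normal(0.0, 1.0, n_samples)
    lam = np.asarray(loadings if loadings is not None else np.ones(n_peptides), float)
    x = lam[:, None] * z + rng.normal(0.0, noise_sd, (len(lam), n_samples))
    return x, z, lam


@pytest.fixture
def make_coherent_group():
    return coherent_group
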