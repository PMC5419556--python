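import numpy as np
import pandas as pd
import pytest

from maldr_age import synthetic_data as sd


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The emulated study cohort: 27 donors, 54 samples, 18 per age group."""
    return sd.simulate_cohort(sd.CohortSpec(seed=7))


@pytest.fixture(scope="session")
def small_genes():
    """A small synthetic annotation shared by fast unit tests."""
    return sd.generate_gene_models(
        sd.SyntheticGenomeSpec(n_genes=12, exons_per_gene=(2, 3)), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
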