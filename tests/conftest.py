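import numpy as np
import pytest

from metaboclust import synthcohort as sc
from metaboclust.preprocess import preprocess


@pytest.fixture(scope="session")
def default_cohort():
    """One default 228-sample spectral cohort (seed 1), shared across tests."""
    config = sc.CohortConfig(seed=1)
    spectra, truth = sc.gen_spectra(config)
    return config, spectra, truth


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    config, spectra, truth = default_cohort
    return config, preprocess(spectra), truth


@pytest.fixture(scope="session")
def expression_cohort(default_cohort):
    """Matched expression matrix + gene sets for the default cohort."""
    _, _, truth = default_cohort
    expr, gene_sets = sc.gen_expression(truth, seed=11)
    return expr, gene_sets, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
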