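import warnings

import numpy as np
import pytest

from twindiff.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: 300 genes, 20 true DE, default pair structure."""
    cfg = SimulationConfig(n_genes=300, n_de_genes=20, n_linked_genes=5, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no case effects anywhere (expression or methylation)."""
    cfg = SimulationConfig(n_genes=300, n_de_genes=0, n_linked_genes=0,
                           meth_case_delta_m=0.0, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
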