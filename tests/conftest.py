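import numpy as np
import pytest

from rqtlscan import SyntheticDesign, plant_differential_epistasis, simulate_standardized_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Small null cohort (no planted signal) shared across tests."""
    design = SyntheticDesign(n_samples=1500, n_studies=4, mafs=(0.3, 0.25, 0.1), seed=11)
    return simulate_standardized_cohort(design)


@pytest.fixture(scope="session")
def epistasis_cohort():
    """Cohort with a strong planted differential-epistasis pair (snp0 x snp1)."""
    base = SyntheticDesign(n_samples=6000, n_studies=4, mafs=(0.3, 0.3, 0.2, 0.4), seed=21)
    design = plant_differential_epistasis(0.6, (0.3, 0.3), base)
    return simulate_standardized_cohort(design)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
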