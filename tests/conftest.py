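import numpy as np
import pandas as pd
import pytest

from drivernet.expression import ExpressionMatrix
from drivernet.synthetic import SimulationConfig, simulate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix():
    """Tiny deterministic expression matrix, no missing values."""
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(6)]
    samples = [f"S{i}" for i in range(20)]
    return ExpressionMatrix(pd.DataFrame(
        rng.standard_normal((6, 20)), index=genes, columns=samples))


@pytest.fixture
def cohort():
    """A moderate synthetic cohort with known partner structure."""
    config = SimulationConfig(n_drivers=4, n_partners_per_driver=2,
                              n_noise=30, n_samples=120, rho=0.8, seed=11)
    matrix, truth = simulate_expression(config)
    return config, matrix, truth
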