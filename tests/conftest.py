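import numpy as np
import pandas as pd
import pytest

from bloodmark.preprocess import filter_low_expression, voom_normalize
from bloodmark.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default planted cohort (seed 1): counts, phenotypes, truth ledger."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_expression(default_cohort):
    counts, _, _ = default_cohort
    return voom_normalize(filter_low_expression(counts))


@pytest.fixture(scope="session")
def small_cohort_config():
    """Reduced cohort for repeated-seed experiments."""
    return dict(n_genes=400, module_sizes=(40,) * 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_expression(rng):
    """50 genes x 12 subjects of iid normal expression."""
    genes = [f"g{i:02d}" for i in range(50)]
    subjects = [f"s{j:02d}" for j in range(12)]
    return pd.DataFrame(rng.standard_normal((50, 12)), index=genes, columns=subjects)
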