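import numpy as np
import pandas as pd
import pytest

from deepdr import imputation, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort used across module tests."""
    cfg = synthetic.SyntheticConfig(
        n_expr_genes=60,
        n_mut_genes=40,
        n_drugs=12,
        n_corpus=300,
        n_cohort=120,
        seed=20240,
    )
    return synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_study():
    cfg = synthetic.SyntheticConfig(
        n_expr_genes=60,
        n_mut_genes=40,
        n_drugs=12,
        n_corpus=300,
        n_cohort=120,
        seed=20240,
    )
    return synthetic.generate_study(cfg)


@pytest.fixture(scope="session")
def imputed_response(small_cohort):
    return imputation.knn_impute_responses(small_cohort.response)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def toy_expression():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{j}" for j in range(8)]
    return pd.DataFrame(
        rng.gamma(2.0, 2.0, size=(20, 8)), index=genes, columns=samples
    )
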