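import numpy as np
import pytest

import spiv
from spiv.preprocess import prepare_model_data


@pytest.fixture(scope="session")
def small_cohort():
    """A 1000-person causal-mode cohort shared across tests."""
    config = spiv.GeneratorConfig(
        n_cases=423, n_controls=577, mode="causal", seed=42
    )
    table, truth = spiv.simulate_cohort(config)
    return table, truth


@pytest.fixture(scope="session")
def small_model_data(small_cohort):
    table, _ = small_cohort
    return prepare_model_data(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
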