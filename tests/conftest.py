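import numpy as np
import pandas as pd
import pytest

from pewas import SimulationConfig, simulate_cohort
from pewas.pipeline import preprocess_bundle


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_samples=150, n_cpgs=240, n_proteins=30, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_cohort(small_config, "discovery")


@pytest.fixture(scope="session")
def small_processed(small_bundle):
    return preprocess_bundle(small_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_matrix(values, scale, prefix="f"):
    """Small OmicsMatrix from a 2-D array."""
    from pewas import OmicsMatrix

    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        pd.DataFrame(
            values,
            index=[f"s{i}" for i in range(values.shape[0])],
            columns=[f"{prefix}{j}" for j in range(values.shape[1])],
        ),
        scale,
    )
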