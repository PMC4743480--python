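import numpy as np
import pytest

from pgpcspr import (Subpopulation, SyntheticSpec, generate_feature_table,
                     generate_toy_molecules)


@pytest.fixture(scope="session")
def toy_molecules():
    return generate_toy_molecules()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_table():
    """Well-separated two-class table (delta=3, n=200)."""
    spec = SyntheticSpec(n_pos=100, n_neg=100, delta=3.0, n_features=5, seed=7)
    table, _ = generate_feature_table(spec)
    return table


@pytest.fixture
def noise_table():
    """Label-independent features (delta=0, n=200)."""
    spec = SyntheticSpec(n_pos=100, n_neg=100, delta=0.0, n_features=5, seed=7)
    table, _ = generate_feature_table(spec)
    return table


@pytest.fixture
def imbalanced_scenario():
    spec = SyntheticSpec(
        n_pos=300, n_neg=200, delta=2.0, seed=11,
        pos_subpopulations=(Subpopulation(0.5, 0.0), Subpopulation(0.5, 0.3)))
    from pgpcspr import generate_imbalanced_scenario
    return generate_imbalanced_scenario(spec)
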