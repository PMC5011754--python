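import numpy as np
import pytest

from csdelm import (
    CostSpec,
    SyntheticSpec,
    fit_ensemble,
    generate,
    train_test_split,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def binary_costs():
    """Asymmetric binary costs: missing the positive class costs 5x."""
    return CostSpec(
        classes=["pos", "neg"],
        cost_matrix=[[0.0, 1.0], [5.0, 0.0]],
        rejection_costs=[0.2, 0.2],
        delta=0.04,
    )


@pytest.fixture(scope="session")
def imbalanced_data():
    """Seeded imbalanced two-class set in the generator's default regime."""
    spec = SyntheticSpec(
        n_samples=400,
        n_features=50,
        class_proportions=(0.3, 0.7),
        effect_size=1.5,
        rng_seed=42,
        class_names=["pos", "neg"],
    )
    return generate(spec)


@pytest.fixture(scope="session")
def blobs():
    """Well-separated two-class data every member should learn easily."""
    spec = SyntheticSpec(
        n_samples=200,
        n_features=10,
        class_proportions=(0.5, 0.5),
        n_informative=10,
        effect_size=4.0,
        rng_seed=7,
        class_names=["a", "b"],
    )
    return generate(spec)


@pytest.fixture(scope="session")
def trained_ensemble(imbalanced_data):
    train, test = train_test_split(imbalanced_data, 300, rng_seed=5)
    ens = fit_ensemble(train, n_members=20, hidden_size=50, rng_seed=11)
    return ens, train, test
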