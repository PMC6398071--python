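"""Shared fixtures: small synthetic QSAR datasets with known ground truth."""

import numpy as np
import pytest

from modesus import SyntheticSpec, generate, partition_dataset


@pytest.fixture(scope="session")
def small_classification():
    """200 x 20 binary-classification set: 3 informative, 2 constant cols."""
    spec = SyntheticSpec(
        n_compounds=200, n_descriptors=20, n_informative=3,
        n_constant=2, noise_sd=0.5, seed=1,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def noiseless_12d():
    """150 x 12 noiseless classification set (2 informative descriptors).

    Zero target noise plus a wide rejection margin around the class
    threshold makes the informative pair perfectly separable at this
    sample size, so exhaustive enumeration of all subsets of size <= 2
    gives a known optimum (zero error) for search-equivalence checks.
    """
    spec = SyntheticSpec(
        n_compounds=150, n_descriptors=12, n_informative=2,
        noise_sd=0.0, margin=0.6, seed=5,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def planted_500x100():
    """The planted-recovery study conditions: 500 compounds, 100
    descriptors, 5 informative, unit effect size, noise sd 0.5."""
    spec = SyntheticSpec(
        n_compounds=500, n_descriptors=100, n_informative=5,
        effect_size=1.0, noise_sd=0.5, seed=0,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_regression():
    spec = SyntheticSpec(
        n_compounds=150, n_descriptors=15, n_informative=3,
        noise_sd=0.2, task="regression", seed=3,
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_split(small_classification):
    ds, _ = small_classification
    return partition_dataset(ds, 0.75, 11)
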