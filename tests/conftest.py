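import numpy as np
import pytest

from daita.models import SoftmaxRegression
from daita.synthetic_data import (
    inject_asymmetric_noise,
    make_synthetic_dataset,
    partition_nodes,
    split_train_validation,
)

NOISE_RATES = {0: 0.5, 1: 0.1}  # cat→dog 50%, dog→cat 10%


@pytest.fixture
def blob_pool():
    """Balanced 2-class Gaussian pool, small enough for fast unit tests."""
    return make_synthetic_dataset(250, "gaussian_blobs", 3.0, seed=11)


@pytest.fixture
def five_nodes(blob_pool):
    """Five noisy stratified nodes plus noisy validation and a clean test set."""
    train, val = split_train_validation(blob_pool, 0.2, seed=1)
    nodes = partition_nodes(train, "even", 5, seed=2)
    for nd in nodes:
        nd.data = inject_asymmetric_noise(nd.data, NOISE_RATES, seed=3)
    noisy_val = inject_asymmetric_noise(val, NOISE_RATES, seed=4)
    test = make_synthetic_dataset(150, "gaussian_blobs", 3.0, seed=12)
    return nodes, noisy_val, test


@pytest.fixture
def linear_factory():
    def factory(seed: int) -> SoftmaxRegression:
        return SoftmaxRegression(2, 2, seed=seed)

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
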