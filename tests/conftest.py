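import numpy as np
import pytest

from ama import (
    EnergyTaskConfig,
    FilterBank,
    LabeledStimulusSet,
    NoiseModel,
    generate_energy_task_set,
)


def random_labeled_set(rng, n_levels=3, per_level=4, d=8, levels=None):
    """Generic random training set: contrast-normalized Gaussian vectors."""
    n = n_levels * per_level
    x = rng.standard_normal((n, d))
    x -= x.mean(axis=1, keepdims=True)
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    labels = np.repeat(np.arange(n_levels), per_level)
    if levels is None:
        levels = np.linspace(-1.0, 1.0, n_levels)
    return LabeledStimulusSet(x, labels, levels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_set(rng):
    return random_labeled_set(rng)


@pytest.fixture
def small_filters(rng, small_set):
    return FilterBank.random(small_set.dim, 2, rng)


@pytest.fixture
def noise():
    return NoiseModel()  # fano 1.36, baseline 0.23


@pytest.fixture(scope="session")
def energy_set():
    """Small synthetic energy-task set shared across tests."""
    return generate_energy_task_set(
        EnergyTaskConfig(d=12, n_levels=4, n_per_level=10,
                         level_range=(-10.0, 10.0), seed=42)
    )
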