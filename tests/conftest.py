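import numpy as np
import pytest

from sizeval import LabeledDataset, SimulationConfig, generate_dataset


def two_class_dataset(class1_rows, class2_rows, labels=("a", "b")):
    """Build a LabeledDataset from explicit per-class row lists."""
    values = np.vstack([np.atleast_2d(class1_rows), np.atleast_2d(class2_rows)])
    y = np.array([labels[0]] * len(class1_rows) + [labels[1]] * len(class2_rows))
    return LabeledDataset(values, y)


def random_dataset(seed, n_vars=None, n_per_class=None):
    """Small random Gaussian two-class dataset (2-10 vars, 4-50 per class)."""
    rng = np.random.default_rng(seed)
    v = n_vars or int(rng.integers(2, 11))
    n = n_per_class or int(rng.integers(4, 51))
    shift = rng.normal(0, 1, size=v)
    x1 = rng.normal(0, 1, size=(n, v))
    x2 = rng.normal(shift, 1, size=(n, v))
    return two_class_dataset(x1, x2)


@pytest.fixture(scope="session")
def good_dataset():
    """Well-separated simulated dataset reused by evaluation tests."""
    config = SimulationConfig(n_per_class=256, n_variables=20, regime="good", seed=42)
    dataset, targets = generate_dataset(config)
    return dataset


@pytest.fixture(scope="session")
def poor_dataset():
    """Barely-separated simulated dataset reused by evaluation tests."""
    config = SimulationConfig(n_per_class=256, n_variables=20, regime="poor", seed=42)
    dataset, targets = generate_dataset(config)
    return dataset
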