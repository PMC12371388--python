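import numpy as np
import pytest

from ilclass import (
    SimulatorConfig,
    SpectralDataset,
    simulate_dataset,
)
from ilclass.preprocess import digitize_dataset


def make_dataset(values, labels, normalized=False, synthetic=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return SpectralDataset(
        values=values,
        labels=np.asarray(labels, dtype=object),
        sample_ids=np.array([f"s{i:03d}" for i in range(n)], dtype=object),
        synthetic=np.zeros(n, dtype=bool) if synthetic is None else np.asarray(synthetic, dtype=bool),
        normalized=normalized,
    )


@pytest.fixture
def tiny_matrix():
    """Nine raw 4-bin spectra, three per class, strictly positive."""
    rng = np.random.default_rng(42)
    values = rng.uniform(10.0, 1e4, size=(9, 4))
    labels = ["BZ"] * 3 + ["PD"] * 3 + ["HR"] * 3
    return make_dataset(values, labels)


@pytest.fixture(scope="session")
def sim_cohort():
    """The default simulated cohort (PD 81, BZ 53, HR 47), digitized."""
    chroms = simulate_dataset(SimulatorConfig(seed=11))
    return digitize_dataset(chroms)


@pytest.fixture(scope="session")
def small_sim_cohort():
    """A smaller digitized cohort for faster classifier-level tests."""
    cfg = SimulatorConfig(n_per_class={"PD": 12, "BZ": 10, "HR": 10}, seed=23)
    return digitize_dataset(simulate_dataset(cfg))
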