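import numpy as np
import pytest

from banditsel.ranking import LabeledTable
from banditsel.synthdata import toy_games


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def games():
    return toy_games()


@pytest.fixture
def separable_table(rng):
    """40 samples, 6 features; feature 0 separates the classes perfectly."""
    n = 40
    labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    values = rng.normal(size=(n, 6))
    values[:, 0] = np.where(labels == 1, 10.0, -10.0) + rng.normal(0, 0.5, n)
    return LabeledTable(
        values=values,
        labels=labels,
        feature_ids=[f"f{j}" for j in range(6)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def noise_table(rng):
    """Balanced labels, all features pure noise."""
    n, p = 40, 8
    return LabeledTable(
        values=rng.normal(size=(n, p)),
        labels=np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)],
        feature_ids=[f"f{j}" for j in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
    )
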