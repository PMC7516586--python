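import numpy as np
import pytest

from emmap import MapCollection, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_dataset():
    """100 synthetic recordings (10 participants x 2 sessions x 5 points)."""
    config = SyntheticConfig(seed=7, n_participants=10, n_sessions=2, n_points=5)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def demo_collection(demo_dataset):
    """Multilevel maps (all three measures) of the demo dataset, normalized."""
    return MapCollection.from_series(demo_dataset).normalize()


def logistic_series(n: int = 2000, x0: float = 0.4) -> np.ndarray:
    """Fully chaotic logistic map x -> 4x(1-x); Lyapunov exponent ln 2."""
    x = np.empty(n)
    x[0] = x0
    for i in range(n - 1):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    return x
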