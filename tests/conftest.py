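import numpy as np
import pandas as pd
import pytest

from stratmark import ExpressionDataset, SimulationConfig, generate


@pytest.fixture(scope="session")
def small_planted():
    """3 correlated blocks of 5, strong effect, plus noise and constants."""
    cfg = SimulationConfig(n_samples=120, n_features=60, n_blocks=3,
                           block_size=5, within_block_correlation=0.9,
                           effect_size=1.5, n_zero_variance=6, rng_seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No signal at all: every feature is exchangeable noise."""
    cfg = SimulationConfig(n_samples=100, n_features=80, n_blocks=0,
                           block_size=1, effect_size=0.0, n_zero_variance=0,
                           rng_seed=3)
    return generate(cfg).dataset


@pytest.fixture
def tiny_dataset():
    """Hand-built 8-sample, 4-feature dataset with an obvious marker."""
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(8)]
    y = pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=samples)
    values = pd.DataFrame(
        {
            "fA": [0.1, 0.2, 0.3, 0.4, 5.1, 5.2, 5.3, 5.4],  # separates classes
            "fB": rng.normal(size=8),
            "fC": rng.normal(size=8),
            "fD": [2.0] * 8,  # constant
        },
        index=samples,
    )
    return ExpressionDataset(values, y)
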