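"""Synthetic expression cohorts with planted statistical structure.

The generator emulates the features of a bulk RNA-seq cohort that the
marker-discovery protocol is designed for: many features of which only a
small minority are informative, blocks of strongly inter-correlated
(mutually redundant) informative features, a class-imbalanced binary
outcome, and a subset of exactly constant (zero-variance) features.

Construction. Each informative block b has a latent factor Z_b ~ N(0,1);
member features are

    x = sqrt(w) * (Z_b + y * delta) + sqrt(1 - w) * eps,   eps ~ N(0,1)

with w = ``within_block_correlation`` and delta = effect_size / sqrt(w),
so that within either class the pairwise correlation of block members is
w and each feature's mean differs between classes by ``effect_size`` in
units of its within-class standard deviation. The class signal rides on
the shared factor, making all block members informative and mutually
redundant — the cluster structure the protocol collapses. Remaining
features are iid N(0,1) noise, except ``n_zero_variance`` constant
columns. Outcome labels are assigned by stratified count (exactly
round(n * positive_fraction) positives), not per-sample Bernoulli draws.

Marginals are Gaussian: the downstream filter discretizes in rank space,
so marginal shape is immaterial to it, and Gaussians admit closed-form
checks of the planted correlations and effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

__all__ = ["SimulationConfig", "SyntheticDataset", "generate", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally impossible."""


#: Outcome prevalence of the motivating cohort (74 positives of 476).
DEFAULT_POSITIVE_FRACTION = 74 / 476


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``n_blocks`` blocks of ``block_size`` correlated informative features
    are planted; ``effect_size`` is the standardized between-class mean
    shift of every informative feature; ``n_zero_variance`` features are
    exactly constant; everything else is independent noise.
    """

    n_samples: int = 300
    n_features: int = 500
    n_blocks: int = 7
    block_size: int = 10
    within_block_correlation: float = 0.9
    effect_size: float = 1.5
    positive_fraction: float = DEFAULT_POSITIVE_FRACTION
    n_zero_variance: int = 55
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigurationError("n_samples must allow >= 2 samples per class")
        if self.n_features <= 0 or self.block_size <= 0:
            raise ConfigurationError("n_features and block_size must be positive")
        if self.n_blocks < 0 or self.n_zero_variance < 0:
            raise ConfigurationError("n_blocks and n_zero_variance must be >= 0")
        if not (0.0 <= self.within_block_correlation < 1.0):
            raise ConfigurationError("within_block_correlation must be in [0, 1)")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ConfigurationError("positive_fraction must be in (0, 1)")
        if self.n_blocks * self.block_size + self.n_zero_variance > self.n_features:
            raise ConfigurationError(
                "block and zero-variance features exceed n_features "
                f"({self.n_blocks}x{self.block_size} + {self.n_zero_variance} "
                f"> {self.n_features})"
            )
        n_pos = int(round(self.n_samples * self.positive_fraction))
        if n_pos < 2 or self.n_samples - n_pos < 2:
            raise ConfigurationError("each class needs >= 2 samples")

    @property
    def n_positive(self) -> int:
        return int(round(self.n_samples * self.positive_fraction))


@dataclass
class SyntheticDataset:
    """A generated cohort plus its ground truth."""

    dataset: ExpressionDataset
    truth: set[str] = field(repr=False)  # planted informative feature IDs
    block_membership: dict[str, int] = field(repr=False)  # feature ID -> block

    @property
    def zero_variance_ids(self) -> list[str]:
        return self.dataset.zero_variance_features()


def _feature_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Generate one synthetic cohort; deterministic for fixed ``rng_seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    n, p = config.n_samples, config.n_features
    n_pos = config.n_positive

    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)

    X = rng.standard_normal((n, p))

    n_informative = config.n_blocks * config.block_size
    # column placement: blocks and constants scattered at random positions
    placement = rng.permutation(p)
    block_cols = placement[:n_informative].reshape(config.n_blocks, -1) \
        if n_informative else np.empty((0, config.block_size), dtype=int)
    zero_cols = placement[n_informative:n_informative + config.n_zero_variance]

    w = config.within_block_correlation
    delta = config.effect_size / np.sqrt(w) if w > 0 else 0.0
    for b in range(config.n_blocks):
        z = rng.standard_normal(n) + y * delta
        cols = block_cols[b]
        if w > 0:
            X[:, cols] = np.sqrt(w) * z[:, None] + np.sqrt(1.0 - w) * X[:, cols]
        else:
            # uncorrelated block: independent features, shifted means
            X[:, cols] += (y * config.effect_size)[:, None]

    if len(zero_cols) > 0:
        X[:, zero_cols] = rng.standard_normal(len(zero_cols))[None, :]

    ids = _feature_ids(p)
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    values = pd.DataFrame(X, index=pd.Index(samples, name="sample_id"),
                          columns=pd.Index(ids, name="feature_id"))
    labels = pd.Series(y, index=values.index, name="label")

    truth: set[str] = set()
    membership: dict[str, int] = {}
    for b in range(config.n_blocks):
        for c in block_cols[b]:
            truth.add(ids[c])
            membership[ids[c]] = b

    return SyntheticDataset(ExpressionDataset(values, labels), truth, membership)
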