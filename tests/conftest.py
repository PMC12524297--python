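"""Shared fixtures: fast training configs and synthetic datasets.

Training-dependent tests use a scaled-down network (fewer epochs, smaller
layers) so the whole suite runs on one CPU in minutes; architectural
invariants do not depend on layer sizes.
"""

import numpy as np
import pytest

from hazchemnet import SyntheticSpec, TrainingConfig, generate_synthetic_features


@pytest.fixture(scope="session")
def fast_cfg() -> TrainingConfig:
    """Small, quick config for pipeline mechanics (not accuracy claims)."""
    return TrainingConfig(ae_epochs=10, moe_epochs=30, hidden_dim=32,
                          latent_dim=8, expert_hidden=8, n_experts=2,
                          batch_size=32, seed=11)


@pytest.fixture(scope="session")
def separable_data():
    """High-separation two-class synthetic features (n=600)."""
    return generate_synthetic_features(SyntheticSpec(n_per_class=300, seed=1))


@pytest.fixture(scope="session")
def small_separable_data():
    """Smaller separable set for quick train/predict round trips."""
    return generate_synthetic_features(SyntheticSpec(n_per_class=100, seed=2))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
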