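"""Shared fixtures: labelled ensembles and trained model sets.

The heavier artifacts (the large filtered ensemble and the trained monomer
model sets) are session-scoped so that validation, dynamics and analysis
tests share one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from aquakrig.geometry import seed_configuration
from aquakrig.kriging import PSOSettings
from aquakrig.models import WaterModelSet
from aquakrig.sampling import (
    EnsembleFilterPolicy,
    compute_normal_modes,
    filter_ensemble,
    sample_configurations,
    split_train_validation,
)
from aquakrig.surrogate import label_ensemble


@pytest.fixture(scope="session")
def seed_config():
    return seed_configuration()


@pytest.fixture(scope="session")
def mode_basis(seed_config):
    return compute_normal_modes(seed_config)


@pytest.fixture(scope="session")
def small_labelled(seed_config, mode_basis):
    """~270 filtered labelled configurations for unit-level checks."""
    configs = sample_configurations(seed_config, 300, rng_seed=11, basis=mode_basis)
    return filter_ensemble(label_ensemble(configs, 7), EnsembleFilterPolicy())


@pytest.fixture(scope="session")
def big_labelled(seed_config, mode_basis):
    """2000 filtered + held-out configurations (validation-scale ensemble)."""
    configs = sample_configurations(seed_config, 3600, rng_seed=21, basis=mode_basis)
    kept = filter_ensemble(label_ensemble(configs, 22), EnsembleFilterPolicy())
    assert len(kept) >= 3000
    return kept[:3000]


@pytest.fixture(scope="session")
def standard_split(big_labelled):
    """The N_trn = 50 split used for the dynamics-facing model set."""
    return split_train_validation(big_labelled, 50, rng_seed=5)


@pytest.fixture(scope="session")
def standard_models(standard_split):
    """N_trn = 50, p = 2 model set (3 energy + 27 moment models).

    The moment models use a lighter swarm: their targets are low-amplitude,
    near-linear functions of the features and converge quickly.
    """
    tr, _ = standard_split
    return WaterModelSet.train(
        tr,
        pso=PSOSettings(swarm_size=40, iterations=150),
        moment_pso=PSOSettings(swarm_size=16, iterations=60),
        rng_seed=2,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
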