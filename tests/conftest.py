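"""Shared fixtures.

The expensive artifacts (a trained network and its training data) are
built once per session at reduced but still realistic scale: 10,000
training decays at SNR 316, two restarts.  Everything else is cheap.
"""

from __future__ import annotations

import numpy as np
import pytest

from phasornet.decay_sim import DecayConfig, generate_training_set
from phasornet.features import extract_features_batch
from phasornet.phasor_net import NetConfig, TrainConfig, train_on_features


@pytest.fixture(scope="session")
def default_config() -> DecayConfig:
    return DecayConfig()


@pytest.fixture(scope="session")
def delta_irf_config() -> DecayConfig:
    """Zero-width IRF: the decay model without instrument blur."""
    return DecayConfig(irf_fwhm=0.0)


@pytest.fixture(scope="session")
def training_set():
    """10,000 simulated decays at SNR 316 under the default protocol ranges."""
    return generate_training_set(n_samples=10_000, seed=20_316)


@pytest.fixture(scope="session")
def training_features(training_set):
    return extract_features_batch(training_set.counts, training_set.config)


@pytest.fixture(scope="session")
def trained_model(training_set, training_features):
    """Network trained once per session (2 restarts, reduced iteration cap)."""
    return train_on_features(
        training_features,
        training_set.params,
        NetConfig(),
        TrainConfig(n_restarts=2, seed=99),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
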