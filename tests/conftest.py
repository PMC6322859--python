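"""Shared fixtures: tiny designs and simulated datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pairrsa as p

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> p.PairDesign:
    return p.random_design(6, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """5 participants, 8 pairs, 16 sensors, short epoch; moderate effect."""
    cfg = p.SimulationConfig(
        n_participants=5,
        n_pairs=8,
        n_sensors=16,
        epoch_window=(-1.2, 0.2),
        word_onsets=(-1.0,),
        seed=21,
    )
    return p.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_static():
    """Noiseless static-identity dataset for exact structural checks."""
    cfg = p.SimulationConfig(
        n_participants=2,
        n_pairs=4,
        n_sensors=12,
        epoch_window=(-1.2, 0.2),
        word_onsets=(-1.0,),
        noise_sd=0.0,
        seed=5,
    )
    return p.simulate_dataset(cfg)
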