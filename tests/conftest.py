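"""Shared fixtures: small synthetic proteins and map bundles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cryotrace as ct

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_protein() -> ct.SyntheticProtein:
    return ct.generate_protein(1, 20, seed=11)


@pytest.fixture(scope="session")
def two_chain_protein() -> ct.SyntheticProtein:
    return ct.generate_protein(2, [20, 30], seed=5)


@pytest.fixture(scope="session")
def bundle(small_protein) -> ct.SyntheticMapBundle:
    return ct.rasterize(small_protein)


@pytest.fixture(scope="session")
def onehot_predictions(bundle) -> ct.PredictionGrids:
    return ct.simulate_predictions(bundle, correct_prob=1.0, noise_seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
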