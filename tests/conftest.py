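"""Shared fixtures: simulated datasets reused across the suite.

The two full-size datasets (one null, one with the gamma effect) are
expensive to build, so they are session-scoped and generated lazily.
"""

from __future__ import annotations

import numpy as np
import pytest

from phonemebci import (
    SimulationConfig,
    build_feature_matrix,
    simulate_dataset,
)

SIM_SEED = 7
CV_SEED = 11


@pytest.fixture(scope="session")
def null_dataset(tmp_path_factory):
    """One participant, 3 sessions x 44 phonemes x 5 trials, no effect, no artifacts."""
    directory = tmp_path_factory.mktemp("sim_null")
    config = SimulationConfig(effect_size=0.0, artifact_rate=0.0, seed=SIM_SEED)
    manifest = simulate_dataset(config, directory)
    return config, manifest


@pytest.fixture(scope="session")
def null_matrix(null_dataset):
    _, manifest = null_dataset
    return build_feature_matrix(manifest, mode="intrasubject", participant=1)


@pytest.fixture(scope="session")
def effect_dataset(tmp_path_factory):
    """Same structure with a strong (effect_size=2) gamma signature on F3/F7."""
    directory = tmp_path_factory.mktemp("sim_effect")
    config = SimulationConfig(effect_size=2.0, artifact_rate=0.0, seed=SIM_SEED)
    manifest = simulate_dataset(config, directory)
    return config, manifest


@pytest.fixture(scope="session")
def effect_matrix(effect_dataset):
    _, manifest = effect_dataset
    return build_feature_matrix(manifest, mode="intrasubject", participant=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
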