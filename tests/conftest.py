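"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from gaitnorm import pipeline
from gaitnorm.synthetic import (
    GeneratorConfig,
    make_profiles,
    synthesize_dataset,
    synthesize_trial,
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_subjects=5, n_trials_per_subject=2, master_seed=11)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return synthesize_dataset(small_config)


@pytest.fixture(scope="session")
def one_trial(small_config):
    profiles = make_profiles(small_config)
    return synthesize_trial(profiles[0], small_config, trial_id=0, subject_index=0)


@pytest.fixture(scope="session")
def cv_dataset():
    """10 subjects x 3 trials: just enough structure for split/tuning tests."""
    cfg = GeneratorConfig(n_subjects=10, n_trials_per_subject=3, master_seed=5)
    trials = synthesize_dataset(cfg)
    X, Y, index = pipeline.build_matrices(trials)
    return X, Y, index


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
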