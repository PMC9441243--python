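"""Shared fixtures: one clean and one noisy synthetic experiment per session."""

import numpy as np
import pytest
from hypothesis import settings

import aphidvision as av
from aphidvision.synthetic import soil_background

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_clean() -> av.GroundTruth:
    return av.GroundTruth()  # noise="none"


@pytest.fixture(scope="session")
def experiment_clean(truth_clean) -> av.ExperimentData:
    return av.generate_trap_experiment(truth_clean, seed=0)


@pytest.fixture(scope="session")
def experiment_poisson() -> av.ExperimentData:
    return av.generate_trap_experiment(
        av.GroundTruth(noise="poisson"), seed=0)


@pytest.fixture(scope="session")
def model_clean(experiment_clean) -> av.SplitRegressionModel:
    return av.fit_choice_model(experiment_clean)


@pytest.fixture(scope="session")
def d65() -> av.Spectrum:
    return av.load_d65()


@pytest.fixture(scope="session")
def soil() -> av.Spectrum:
    return soil_background()


@pytest.fixture(scope="session")
def leaves_clean() -> list:
    return av.generate_leaf_set(seed=0, noise_sd=0.0)


def count_true(flags) -> int:
    return int(np.sum(np.asarray(flags, dtype=bool)))
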