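import numpy as np
import pytest

from mnsox import ProfileTruth, TraceTruth, make_profiles, make_trace


@pytest.fixture(scope="session")
def default_truth():
    """The standard 8 pre- + 3 post-pasteurization 30 uM spike experiment."""
    return TraceTruth.default_experiment(seed=42)


@pytest.fixture(scope="session")
def noisy_trace(default_truth):
    return make_trace(default_truth)


@pytest.fixture(scope="session")
def noiseless_trace():
    truth = TraceTruth.default_experiment(seed=0, noise_sd=0.0)
    return make_trace(truth)


@pytest.fixture(scope="session")
def synthetic_profile():
    return make_profiles(ProfileTruth())
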