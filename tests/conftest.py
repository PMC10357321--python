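import numpy as np
import pytest

from kinread.config import GeneratorConfig
from kinread import synth
from kinread.kinematics import zscore_features


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_primes(default_config):
    return synth.generate_primes(default_config)


@pytest.fixture(scope="session")
def default_features(default_primes):
    return synth.prime_features(default_primes)


@pytest.fixture(scope="session")
def default_zfeatures(default_features):
    return zscore_features(default_features)


@pytest.fixture(scope="session")
def default_perceivers(default_config, default_primes):
    return synth.generate_perceivers(
        default_config, default_primes.ground_truth.true_encoding_direction
    )


@pytest.fixture(scope="session")
def default_choices(default_config, default_primes, default_perceivers):
    return synth.simulate_discrimination(
        default_primes, default_perceivers, default_config
    )


@pytest.fixture(scope="session")
def small_config():
    """Reduced design used by the heavier analysis tests."""
    return GeneratorConfig(seed=7, n_perceivers=6, n_priming_trials=120)


@pytest.fixture(scope="session")
def small_session(small_config):
    primes = synth.generate_primes(small_config)
    perceivers = synth.generate_perceivers(
        small_config, primes.ground_truth.true_encoding_direction
    )
    trials = synth.simulate_priming_session(primes, perceivers, small_config)
    index = synth.true_predictors(primes, perceivers)[
        ["perceiver_id", "prime_id", "true_readout"]
    ]
    return {"primes": primes, "perceivers": perceivers, "trials": trials, "index": index}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
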