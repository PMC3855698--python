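import numpy as np
import pytest

from dyadrl.synthetic_data import (
    ObserverParams,
    SessionConfig,
    default_thresholds,
    simulate_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def observer():
    return ObserverParams(bias=0.0, sigma=0.1, conf_thresholds=default_thresholds(0.1))


@pytest.fixture
def escalating_observer():
    return ObserverParams(
        bias=0.0, sigma=0.1, conf_thresholds=default_thresholds(0.1), escalation_rate=0.005
    )


@pytest.fixture
def default_config(observer):
    other = ObserverParams(bias=0.0, sigma=0.08, conf_thresholds=default_thresholds(0.08))
    return SessionConfig(members=(observer, other), seed=7)


@pytest.fixture
def session(default_config):
    return simulate_session(default_config)
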