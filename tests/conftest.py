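import numpy as np
import pytest

from neozy.synthetic_data import (
    FactorialGenConfig,
    SemiFieldGenConfig,
    TimeCourseGenConfig,
    default_surface,
    simulate_factorial,
    simulate_semifield,
    simulate_timecourse,
)


@pytest.fixture(scope="session")
def surface():
    return default_surface()


@pytest.fixture(scope="session")
def factorial_records():
    return simulate_factorial(FactorialGenConfig(seed=42))


@pytest.fixture(scope="session")
def timecourse_records():
    return simulate_timecourse(TimeCourseGenConfig(seed=42))


@pytest.fixture(scope="session")
def semifield_data():
    return simulate_semifield(SemiFieldGenConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
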