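import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def observer():
    from trpsem.observers import ObserverParams
    return ObserverParams(
        subject=0,
        mdd_log_threshold=np.array([1.25, 1.35, 1.46, 1.56]),
        dd_jnd_empty=16.3, dd_jnd_filled=7.8, tg_sd=6.6, rp_jnd=49.6)


@pytest.fixture
def smooth_observer():
    """Observer whose JNDs are large relative to the staircase steps, so
    the tracked level stays in the near-linear region of the psychometric
    function."""
    from trpsem.observers import ObserverParams
    return ObserverParams(
        subject=1,
        mdd_log_threshold=np.array([1.25, 1.35, 1.46, 1.56]),
        dd_jnd_empty=50.0, dd_jnd_filled=50.0, tg_sd=6.6, rp_jnd=50.0)


@pytest.fixture(scope="session")
def measure_data():
    """Measure-level data from the fixed-links generative model."""
    from trpsem.models import generate_measure_level_data
    rng = np.random.default_rng(77)
    return generate_measure_level_data(273, rng)
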