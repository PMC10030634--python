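import pytest

from beeheat import SyntheticConfig, generate_visits


@pytest.fixture(scope="session")
def small_visits():
    """150 synthetic visits, enough to fit every variant quickly."""
    visits, _ = generate_visits(SyntheticConfig(n_visits=150, seed=7))
    return visits


@pytest.fixture(scope="session")
def full_visits():
    """A full-size (872-visit) synthetic dataset at the default calibration."""
    visits, _ = generate_visits(SyntheticConfig(seed=1))
    return visits
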