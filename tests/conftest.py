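import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import urbiflux as uf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

START = dt.date(2015, 5, 1)


@pytest.fixture(scope="session")
def arid_forcing():
    """Five arid summer days, fixed seed."""
    return uf.synthesize_forcing("arid", START, 5, seed=7)


@pytest.fixture(scope="session")
def arid_surface():
    """Packaged (soil, policy, tiles, weights) for the arid archetype."""
    return uf.default_surface("arid")


@pytest.fixture(scope="session")
def arid_run(arid_forcing, arid_surface):
    soil, policy, tiles, weights = arid_surface
    return uf.run_paired(arid_forcing, soil, policy, tiles, weights)
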