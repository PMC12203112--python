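import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

from imic import IMICConfig, solve_imic, to_irreversible
from imic.expression import correction_factors
from imic.fixtures import (FixtureSpec, make_expression, make_kink_toy,
                           make_toy_community)


@pytest.fixture(scope="session")
def config():
    return IMICConfig()


@pytest.fixture(scope="session")
def kink_toy():
    """Single-member chain whose z*(lambda) kinks exactly at lambda = 10."""
    model, profile = make_kink_toy()
    return model, correction_factors(model, profile)


@pytest.fixture(scope="session")
def chain4():
    """The 4-member cross-feeding community at the default study conditions."""
    spec = FixtureSpec(seed=0)
    assembled, truth = make_toy_community(spec)
    model = to_irreversible(assembled)
    factors = correction_factors(model, make_expression(spec))
    return spec, model, truth, factors


@pytest.fixture(scope="session")
def chain4_solution(chain4, config):
    _, model, _, factors = chain4
    return solve_imic(model, factors, config, lam=10.0)
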