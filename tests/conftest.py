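import pytest
from hypothesis import HealthCheck, settings

import bayesni as b

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base():
    """18% expected failure both arms (Beta(66,302) design), flat analysis
    priors, fixed 10% margin, alpha 0.05."""
    return b.load_scenario("odyssey-base")


@pytest.fixture(scope="session")
def skeptical():
    """Analysis priors favouring inferiority: experimental Beta(141,362),
    control Beta(66,302)."""
    return b.load_scenario("odyssey-skeptical")


@pytest.fixture(scope="session")
def enthusiastic():
    """Beta(11,48) analysis priors on both arms (strongly favour NI)."""
    return b.load_scenario("odyssey-enthusiastic")


@pytest.fixture(scope="session")
def degenerate():
    """Near-point-mass Beta(6600,30200) design priors at 18%."""
    return b.load_scenario("odyssey-degenerate-design")


@pytest.fixture(scope="session")
def margin_u0812():
    return b.load_scenario("odyssey-margin-u0812")


@pytest.fixture(scope="session")
def margin_u0515():
    return b.load_scenario("odyssey-margin-u0515")
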