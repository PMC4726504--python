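import pytest

from nutrisupply.synthetic import FixtureSpec, country_x_fixture, generate_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world: 3 countries, 2 years, no nes."""
    return generate_world(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def estimated_world():
    """World with estimated/imputed nes fruit supplies (redistribution path)."""
    return generate_world(FixtureSpec(seed=13, nes_scenario="estimated"))


@pytest.fixture(scope="session")
def sparse_world():
    """World with one sparse reporter (exclusion path)."""
    return generate_world(FixtureSpec(seed=7, nes_scenario="sparse"))


@pytest.fixture()
def country_x():
    return country_x_fixture()
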