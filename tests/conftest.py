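import numpy as np
import pytest

from efmdec import builtin_fixtures, enumerate_efms_bruteforce


@pytest.fixture(scope="session")
def fixture_specs():
    return {spec.name: spec for spec in builtin_fixtures()}


@pytest.fixture(scope="session")
def chain(fixture_specs):
    return fixture_specs["chain"].model


@pytest.fixture(scope="session")
def diamond(fixture_specs):
    return fixture_specs["diamond"].model


@pytest.fixture(scope="session")
def rev_cycle(fixture_specs):
    return fixture_specs["rev_cycle"].model


@pytest.fixture(scope="session")
def rev_branch(fixture_specs):
    return fixture_specs["rev_branch"].model


@pytest.fixture(scope="session")
def dual_demand(fixture_specs):
    return fixture_specs["dual_demand"].model


@pytest.fixture(scope="session")
def oracle_sets(fixture_specs):
    """Brute-force EFM sets for every builtin fixture, enumerated once."""
    return {name: enumerate_efms_bruteforce(spec.model)
            for name, spec in fixture_specs.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
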