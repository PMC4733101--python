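import pytest

from smscost import m4rh_2014, promo_cost_per_user


@pytest.fixture(scope="session")
def baseline():
    """The 2014 inputs: (ledger, traffic, scenario presets, uncertainty config)."""
    return m4rh_2014()


@pytest.fixture(scope="session")
def ledger(baseline):
    return baseline[0]


@pytest.fixture(scope="session")
def traffic(baseline):
    return baseline[1]


@pytest.fixture(scope="session")
def presets(baseline):
    return baseline[2]


@pytest.fixture(scope="session")
def ucfg(baseline):
    return baseline[3]


@pytest.fixture(scope="session")
def f0(ledger):
    """Fixed costs excluding promotion: 75,147 - 19,400 = 55,747."""
    return ledger.fixed_excl_promo


@pytest.fixture(scope="session")
def promo(ledger, traffic):
    """Promotional cost per user carried at exactly $0.15."""
    return promo_cost_per_user(ledger, traffic)
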