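import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smscost import (
    CostItem,
    CostLedger,
    LedgerError,
    TrafficProfile,
    cost_per_user,
    export_ledger_csv,
    promo_cost_per_user,
    read_ledger,
    round_usd,
    total_fixed_cost,
    total_program_cost,
    total_variable_cost,
    write_ledger,
)

SMS_ITEM = CostItem("SMS costs", "sms", "variable")


def make_ledger(amounts, unit_cost=0.032):
    items = tuple(
        CostItem(f"item{i}", cat, "fixed", a)
        for i, (cat, a) in enumerate(amounts)
    ) + (SMS_ITEM,)
    return CostLedger(items, unit_cost)


class TestBaselineTotals:
    def test_fixed_total(self, ledger):
        assert total_fixed_cost(ledger) == 75_147

    def test_variable_cost(self, ledger, traffic):
        assert total_variable_cost(ledger, traffic) == pytest.approx(128_327.68)
        assert round_usd(total_variable_cost(ledger, traffic)) == 128_328

    def test_total_program_cost(self, ledger, traffic):
        assert round_usd(total_program_cost(ledger, traffic)) == 203_475

    def test_cost_per_user(self, ledger, traffic):
        assert cost_per_user(ledger, traffic) == 1.62

    def test_promo_per_user_carried_at_two_decimals(self, ledger, traffic):
        # 19,400 / 125,320 = 0.1548... but the analyses carry exactly 0.15
        assert promo_cost_per_user(ledger, traffic) == 0.15

    def test_fixed_excl_promo(self, ledger):
        assert ledger.fixed_excl_promo == 55_747


class TestEdgeCases:
    def test_empty_fixed_section_sums_to_zero(self):
        assert total_fixed_cost(make_ledger([])) == 0

    def test_single_item(self):
        assert total_fixed_cost(make_ledger([("technology", 100)])) == 100

    def test_zero_users_gives_fixed_only(self, ledger):
        t = TrafficProfile(8, 24, 0)
        assert total_variable_cost(ledger, t) == 0
        assert total_program_cost(ledger, t) == total_fixed_cost(ledger)

    def test_hand_multiplied_variable_cost(self):
        led = make_ledger([], unit_cost=0.01)
        assert total_variable_cost(led, TrafficProfile(5, 5, 100)) == pytest.approx(10)

    def test_cost_per_user_without_fixed_costs(self):
        led = make_ledger([], unit_cost=0.01)
        for users in (1, 50, 125_320):
            assert cost_per_user(led, TrafficProfile(8, 24, users)) == 0.32

    def test_cost_per_user_fixed_only(self):
        led = make_ledger([("personnel", 100)], unit_cost=0.0)
        assert cost_per_user(led, TrafficProfile(0, 0, 1)) == 100

    def test_promo_hand_division(self):
        led = make_ledger([("promotion", 150)])
        assert promo_cost_per_user(led, TrafficProfile(8, 24, 1000)) == 0.15
        led0 = make_ledger([("technology", 10)])
        assert promo_cost_per_user(led0, TrafficProfile(8, 24, 1000)) == 0


class TestValidation:
    def test_negative_amount_rejected(self):
        with pytest.raises(LedgerError):
            CostItem("bad", "technology", "fixed", -1.0)

    def test_exactly_one_sms_item_required(self):
        with pytest.raises(LedgerError):
            CostLedger((CostItem("t", "technology", "fixed", 1.0),), 0.03)
        with pytest.raises(LedgerError):
            CostLedger((SMS_ITEM, SMS_ITEM), 0.03)

    def test_zero_users_cost_per_user_raises(self, ledger):
        with pytest.raises(LedgerError):
            cost_per_user(ledger, TrafficProfile(8, 24, 0))
        with pytest.raises(LedgerError):
            promo_cost_per_user(ledger, TrafficProfile(8, 24, 0))

    def test_traffic_sent_fraction(self, traffic):
        assert traffic.sms_total_per_user == 32
        assert traffic.sent_fraction == 0.25


@settings(deadline=None, derandomize=True)
@given(
    amounts=st.lists(
        st.floats(min_value=0, max_value=1e6, allow_nan=False), max_size=6
    ),
    unit=st.floats(min_value=0, max_value=1, allow_nan=False),
    sms=st.floats(min_value=0, max_value=100, allow_nan=False),
    users=st.floats(min_value=0, max_value=1e7, allow_nan=False),
)
def test_cost_conservation_and_linearity(amounts, unit, sms, users):
    """Total cost is exactly fixed + variable, and the variable part is
    linear in the user volume."""
    led = make_ledger([("technology", a) for a in amounts], unit)
    t = TrafficProfile(sms / 4, 3 * sms / 4, users)
    assert total_program_cost(led, t) == total_fixed_cost(led) + total_variable_cost(led, t)
    t2 = TrafficProfile(sms / 4, 3 * sms / 4, 2 * users)
    assert total_variable_cost(led, t2) == pytest.approx(2 * total_variable_cost(led, t))
    # doubling users doubles only the variable part
    assert total_program_cost(led, t2) == pytest.approx(
        total_fixed_cost(led) + 2 * total_variable_cost(led, t)
    )


def test_ledger_file_round_trip(ledger, traffic, tmp_path):
    """A ledger written to file and re-read yields identical totals, and
    re-serialising reproduces the file byte for byte."""
    path = tmp_path / "ledger.yaml"
    write_ledger(ledger, path)
    again = read_ledger(path)
    assert total_fixed_cost(again) == total_fixed_cost(ledger)
    assert total_program_cost(again, traffic) == total_program_cost(ledger, traffic)
    first = path.read_text()
    write_ledger(again, path)
    assert path.read_text() == first


def test_packaged_ledger_reserializes_identically(ledger, tmp_path):
    from importlib import resources

    shipped = (
        resources.files("smscost.data").joinpath("ledger_2014.yaml").read_text()
    )
    path = tmp_path / "ledger.yaml"
    write_ledger(ledger, path)
    import yaml

    assert yaml.safe_load(path.read_text()) == yaml.safe_load(shipped)


def test_csv_export(ledger, tmp_path):
    import csv

    path = tmp_path / "ledger.csv"
    export_ledger_csv(ledger, path)
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    assert {r["category"] for r in rows} == {
        "technology", "administration", "personnel", "promotion", "sms"
    }
    total = sum(float(r["amount"]) for r in rows if r["classification"] == "fixed")
    assert total == 75_147


def test_malformed_ledger_file_raises(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("just a string\n")
    with pytest.raises(LedgerError):
        read_ledger(path)
    path.write_text("fixed: {}\n")
    with pytest.raises(LedgerError):
        read_ledger(path)


@pytest.mark.parametrize(
    "x,expected",
    [(128_327.68, 128_328), (-34_442.6, -34_443), (5_659.8, 5_660),
     (-84_570.6, -84_571), (2.5, 3), (-2.5, -3), (0.0, 0)],
)
def test_round_usd_half_away_from_zero(x, expected):
    assert round_usd(x) == expected
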