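"""Annual program cost ledger: fixed/variable decomposition and baseline totals.

A national on-demand SMS health service has two kinds of annual cost:

* **fixed** — technology (servers, short-code and network fees, technical
  support), administration, personnel and promotion, which do not vary with
  the number of users; and
* **variable** — per-SMS delivery charges paid to the mobile network
  operator, proportional to total SMS traffic
  (``unit cost × SMS per user × users``).

The 2014 m4RH Tanzania baseline — the donor-funded year these models start
from — had fixed costs of $75,147, an SMS unit cost of $0.032, and 125,320
users averaging 8 SMS sent and 24 received, giving a variable cost of
$128,328, a total of $203,475 and a cost of $1.62 per user.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "CATEGORIES",
    "CostItem",
    "CostLedger",
    "TrafficProfile",
    "LedgerError",
    "total_fixed_cost",
    "total_variable_cost",
    "total_program_cost",
    "cost_per_user",
    "promo_cost_per_user",
    "round_usd",
    "round_cents",
    "read_ledger",
    "write_ledger",
    "export_ledger_csv",
]

#: Recognised cost categories. ``sms`` is the single variable item.
CATEGORIES = ("technology", "administration", "personnel", "promotion", "sms")


class LedgerError(ValueError):
    """Raised for an invalid ledger, cost item or traffic profile."""


def round_usd(x: float) -> int:
    """Round to whole dollars, halves away from zero (report-time only)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def round_cents(x: float) -> float:
    """Round to cents, halves away from zero."""
    return math.copysign(math.floor(abs(x) * 100 + 0.5), x) / 100


@dataclass(frozen=True)
class CostItem:
    """One ledger line: a named annual cost in a category.

    Fixed items carry an ``annual_amount`` in USD/year; the single variable
    ``sms`` item carries none (its cost is ``unit cost × traffic``, computed
    from a :class:`TrafficProfile`).
    """

    name: str
    category: str
    classification: str  # "fixed" | "variable"
    annual_amount: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LedgerError(f"unknown category {self.category!r}")
        if self.classification not in ("fixed", "variable"):
            raise LedgerError(f"unknown classification {self.classification!r}")
        if self.classification == "fixed":
            if self.annual_amount is None:
                raise LedgerError(f"fixed item {self.name!r} needs an amount")
            if self.annual_amount < 0:
                raise LedgerError(f"negative amount for {self.name!r}")
        elif self.annual_amount is not None:
            raise LedgerError("variable sms item must not carry an annual amount")


@dataclass(frozen=True)
class CostLedger:
    """Itemised annual costs plus the per-SMS delivery rate.

    Category totals are stored as given, never recomputed from finer
    sub-lines, so that every downstream figure is consistent with the
    stated fixed total.
    """

    items: tuple[CostItem, ...]
    sms_unit_cost: float

    def __post_init__(self) -> None:
        if self.sms_unit_cost < 0:
            raise LedgerError("sms_unit_cost must be >= 0")
        n_sms = sum(
            1
            for it in self.items
            if it.category == "sms" and it.classification == "variable"
        )
        if n_sms != 1:
            raise LedgerError(
                f"ledger needs exactly one variable sms item, found {n_sms}"
            )

    @property
    def fixed_items(self) -> tuple[CostItem, ...]:
        return tuple(it for it in self.items if it.classification == "fixed")

    @property
    def total_fixed(self) -> float:
        return sum(it.annual_amount for it in self.fixed_items)

    @property
    def promo_total(self) -> float:
        """Annual promotion spend, USD/year."""
        return sum(
            it.annual_amount for it in self.fixed_items if it.category == "promotion"
        )

    @property
    def fixed_excl_promo(self) -> float:
        """Fixed costs with promotion taken out (promotion is re-classed as a
        per-user variable cost in the break-even analyses)."""
        return self.total_fixed - self.promo_total


@dataclass(frozen=True)
class TrafficProfile:
    """Per-user SMS counts and the user volume they apply to.

    2014 baseline: 8 sent, 24 received (32 total, a 1:3 sent:received
    ratio) across 125,320 unique users.
    """

    sms_sent_per_user: float
    sms_received_per_user: float
    users: float

    def __post_init__(self) -> None:
        if min(self.sms_sent_per_user, self.sms_received_per_user, self.users) < 0:
            raise LedgerError("traffic fields must be >= 0")

    @property
    def sms_total_per_user(self) -> float:
        return self.sms_sent_per_user + self.sms_received_per_user

    @property
    def sent_fraction(self) -> float:
        """Share of all SMS that users send (2014: 0.25, i.e. 1:3)."""
        total = self.sms_total_per_user
        return self.sms_sent_per_user / total if total else 0.0

    def scaled_to_total(self, sms_total: float) -> "TrafficProfile":
        """Same sent:received split, rescaled to a new per-user total."""
        f = self.sent_fraction if self.sms_total_per_user else 0.25
        return TrafficProfile(f * sms_total, (1 - f) * sms_total, self.users)


# ---------------------------------------------------------------------------
# Aggregation operations
# ---------------------------------------------------------------------------

def total_fixed_cost(ledger: CostLedger) -> float:
    """Sum of all fixed items' annual amounts, USD/year."""
    return ledger.total_fixed


def total_variable_cost(ledger: CostLedger, traffic: TrafficProfile) -> float:
    """SMS delivery cost: ``unit cost × SMS per user × users``."""
    return ledger.sms_unit_cost * traffic.sms_total_per_user * traffic.users


def total_program_cost(ledger: CostLedger, traffic: TrafficProfile) -> float:
    """Fixed plus variable annual cost; round to whole USD only for reports."""
    return total_fixed_cost(ledger) + total_variable_cost(ledger, traffic)


def cost_per_user(ledger: CostLedger, traffic: TrafficProfile) -> float:
    """Total annual cost divided by users, reported to cents."""
    if traffic.users <= 0:
        raise LedgerError("cost_per_user undefined for zero users")
    return round_cents(total_program_cost(ledger, traffic) / traffic.users)


def promo_cost_per_user(ledger: CostLedger, traffic: TrafficProfile) -> float:
    """Promotion spend per user, rounded to cents.

    The two-decimal value (2014: 19,400 / 125,320 → $0.15) is carried
    forward exactly into the break-even analyses.
    """
    if traffic.users <= 0:
        raise LedgerError("promo_cost_per_user undefined for zero users")
    return round_cents(ledger.promo_total / traffic.users)


# ---------------------------------------------------------------------------
# Ledger file I/O
#
# The on-disk format is YAML with one mapping per category section, e.g.
#
#   fixed:
#     technology: {"Technology costs": 21000}
#   variable:
#     sms_unit_cost: 0.032
# ---------------------------------------------------------------------------

def _ledger_to_mapping(ledger: CostLedger) -> dict:
    fixed: dict[str, dict[str, float]] = {}
    for it in ledger.fixed_items:
        fixed.setdefault(it.category, {})[it.name] = it.annual_amount
    sms_item = next(it for it in ledger.items if it.category == "sms")
    return {
        "fixed": fixed,
        "variable": {"sms_unit_cost": ledger.sms_unit_cost,
                     "sms_item": sms_item.name},
    }


def _ledger_from_mapping(doc: dict) -> CostLedger:
    try:
        fixed = doc["fixed"]
        variable = doc["variable"]
        unit_cost = float(variable["sms_unit_cost"])
    except (KeyError, TypeError) as exc:
        raise LedgerError(f"malformed ledger file: missing {exc}") from exc
    items: list[CostItem] = []
    for category, lines in fixed.items():
        for name, amount in lines.items():
            items.append(CostItem(name, category, "fixed", float(amount)))
    items.append(CostItem(variable.get("sms_item", "SMS costs"), "sms", "variable"))
    return CostLedger(tuple(items), unit_cost)


def write_ledger(ledger: CostLedger, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_ledger_to_mapping(ledger), sort_keys=False)
    )


def read_ledger(path: str | Path) -> CostLedger:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise LedgerError(f"malformed ledger file {path}: expected a mapping")
    return _ledger_from_mapping(doc)


def export_ledger_csv(ledger: CostLedger, path: str | Path) -> None:
    """Write the cost table as CSV: category, item, classification, amount."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "item", "classification", "amount"])
        for it in ledger.items:
            amount = "" if it.annual_amount is None else f"{it.annual_amount:g}"
            w.writerow([it.category, it.name, it.classification, amount])
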