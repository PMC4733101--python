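"""Pay-for-service cost-recovery scenarios and their per-user economics.

Each scenario fixes a user-facing SMS price ``p`` (held at the 2014 standard
Tanzanian rate, $0.03), a negotiated bulk rate ``c`` the program pays the
mobile network operator per SMS, and whether users pay only for the messages
they send or for every message sent *and* received.

Canonical model
---------------
The program earns the margin ``m = p − c`` on every SMS the user pays for
and pays the bulk rate ``c`` to deliver every SMS the user does not pay
for.  Per user, with ``s`` messages sent and ``r`` received:

* user pays all:        ``net/user = m · (s + r)``
* user pays sent only:  ``net/user = m · s − c · r``

At a volume ``U`` with promotion treated as a per-user variable cost
``promo`` and remaining fixed costs ``F0``::

    net(U) = U · (net/user − promo) − F0

The four standard scenarios are presets: bulk rate $0.02 (scenarios 1–2)
or $0.01 (scenarios 3–4), users paying sent-only (1, 3) or all SMS (2, 4).

Replication variant
-------------------
The published scenario-1 figures (net −$94,596 at 125,320 users; user costs
of $0.16 and $0.64 for scenarios 1–2) are arithmetically inconsistent with
that scenario's stated $0.02 bulk rate: they follow only if both the
delivery rate and the user-side price are taken as one tier lower ($0.01
delivery, $0.02 user price).  Rather than silently mixing conventions, the
canonical model above is used everywhere, and the published variant is
exposed separately as :data:`SCENARIO_1_REPLICATION` /
:func:`net_at_volume_replication_s1`, clearly labeled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cost_ledger import TrafficProfile, round_cents

__all__ = [
    "ScenarioSpec",
    "ScenarioOutcome",
    "SCENARIOS",
    "SCENARIO_1_REPLICATION",
    "scenario_presets",
    "per_user_sms_net",
    "net_at_volume",
    "net_at_volume_replication_s1",
    "avg_user_cost",
    "reduction_vs_baseline",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A pricing scenario: user price, program bulk rate, payment structure."""

    label: str
    user_price: float  # USD per SMS the user pays (p)
    program_rate: float  # USD per SMS the program pays the operator (c)
    user_pays_received: bool  # False: user pays sent-only

    def __post_init__(self) -> None:
        if not 0 <= self.program_rate <= self.user_price:
            raise ValueError(
                f"{self.label}: need user_price >= program_rate >= 0, got "
                f"p={self.user_price}, c={self.program_rate}"
            )

    @property
    def margin(self) -> float:
        """Per-SMS profit margin m = p − c on user-paid messages."""
        return self.user_price - self.program_rate


@dataclass(frozen=True)
class ScenarioOutcome:
    """Net result of a scenario at a given volume (full precision; profit
    positive, cost negative — round only when reporting)."""

    label: str
    net_usd: float
    per_user_sms_net: float
    avg_user_cost: float


SCENARIOS: dict[str, ScenarioSpec] = {
    "scenario1": ScenarioSpec("scenario1", 0.03, 0.02, user_pays_received=False),
    "scenario2": ScenarioSpec("scenario2", 0.03, 0.02, user_pays_received=True),
    "scenario3": ScenarioSpec("scenario3", 0.03, 0.01, user_pays_received=False),
    "scenario4": ScenarioSpec("scenario4", 0.03, 0.01, user_pays_received=True),
}

#: Published-figure variant of scenario 1 (see module docstring): one tier
#: lower on both sides (p = 0.02, c = 0.01), user pays sent-only.  Under the
#: canonical formula this reproduces the printed net (−$94,596) and printed
#: scenario-1 user cost ($0.16).
SCENARIO_1_REPLICATION = ScenarioSpec(
    "scenario1-replication", 0.02, 0.01, user_pays_received=False
)


def scenario_presets(replication_mode: bool = False) -> dict[str, ScenarioSpec]:
    """The four named presets; with ``replication_mode`` scenario 1 is the
    published-figure variant."""
    presets = dict(SCENARIOS)
    if replication_mode:
        presets["scenario1"] = SCENARIO_1_REPLICATION
    return presets


def per_user_sms_net(spec: ScenarioSpec, traffic: TrafficProfile) -> float:
    """SMS-side net revenue per user, USD.

    Margin on every user-paid SMS, minus delivery cost for SMS the user
    does not pay for.
    """
    s, r = traffic.sms_sent_per_user, traffic.sms_received_per_user
    if spec.user_pays_received:
        return spec.margin * (s + r)
    return spec.margin * s - spec.program_rate * r


def net_at_volume(
    spec: ScenarioSpec,
    traffic: TrafficProfile,
    fixed_excl_promo: float,
    promo_per_user: float,
) -> ScenarioOutcome:
    """Annual net profit (+) or cost (−) at ``traffic.users`` users.

    Promotion enters as a variable cost per user; ``fixed_excl_promo`` is
    the remaining fixed cost (2014: 75,147 − 19,400 = 55,747).
    """
    if fixed_excl_promo < 0:
        raise ValueError("fixed_excl_promo must be >= 0")
    pun = per_user_sms_net(spec, traffic)
    net = traffic.users * (pun - promo_per_user) - fixed_excl_promo
    return ScenarioOutcome(spec.label, net, pun, avg_user_cost(spec, traffic))


def net_at_volume_replication_s1(
    traffic: TrafficProfile,
    fixed_excl_promo: float,
    promo_per_user: float,
) -> float:
    """Published-figure scenario-1 net: margin $0.01 on sent SMS, delivery
    at $0.01 per received SMS (2014 inputs → −$94,596).

    Kept as an explicit formula so the replication convention is visible;
    equals ``net_at_volume(SCENARIO_1_REPLICATION, ...)``.
    """
    s, r = traffic.sms_sent_per_user, traffic.sms_received_per_user
    pun = 0.01 * s - 0.01 * r
    return traffic.users * (pun - promo_per_user) - fixed_excl_promo


def avg_user_cost(spec: ScenarioSpec, traffic: TrafficProfile) -> float:
    """Average annual cost to a user: price × number of SMS the user pays
    for (sent-only, or sent + received), reported to cents."""
    n = traffic.sms_total_per_user if spec.user_pays_received else traffic.sms_sent_per_user
    return round_cents(spec.user_price * n)


def reduction_vs_baseline(net: float, baseline_cost: float) -> float:
    """Fraction of the baseline program cost no longer borne by the program.

    For a shortfall (net ≤ 0) this is ``1 − |net| / baseline``; a positive
    net means the cost is fully recovered and the reduction is 1.0.
    """
    if baseline_cost <= 0:
        raise ValueError("baseline_cost must be > 0")
    if net > 0:
        return 1.0
    return 1.0 - abs(net) / baseline_cost
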