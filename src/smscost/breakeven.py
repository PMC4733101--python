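"""Break-even user volume: where annual revenue equals annual cost.

With promotion treated as a per-user variable cost, the net outcome is
affine in the user volume U::

    net(U) = U * (per_user_sms_net - promo_per_user) - fixed_excl_promo

so the break-even volume has the closed form
``U* = fixed_excl_promo / (per_user_sms_net - promo_per_user)`` whenever the
per-user net margin is positive.  When it is zero or negative the shortfall
only grows with additional users and break-even is declared infeasible — a
typed result, not an error.

A numeric root finder (bisection on net(U) = 0) is provided as an
independent cross-check of the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import bisect

from .cost_ledger import TrafficProfile
from .scenarios import ScenarioSpec, net_at_volume, per_user_sms_net

__all__ = ["BreakevenResult", "breakeven_volume", "breakeven_volume_numeric"]

_BRACKET_MAX = 1e9  # search ceiling for the numeric solver, in users


@dataclass(frozen=True)
class BreakevenResult:
    """Break-even volume (whole users) or infeasibility, with the per-user
    net margin that decided it."""

    feasible: bool
    volume: int | None
    margin_per_user: float

    def __str__(self) -> str:  # mirrors the report wording
        return f"{self.volume:,}" if self.feasible else "Not possible"


def _margin(spec: ScenarioSpec, traffic: TrafficProfile, promo_per_user: float) -> float:
    return per_user_sms_net(spec, traffic) - promo_per_user


def breakeven_volume(
    spec: ScenarioSpec,
    traffic: TrafficProfile,
    fixed_excl_promo: float,
    promo_per_user: float,
) -> BreakevenResult:
    """Closed-form break-even volume, rounded to the nearest whole user.

    2014 presets: scenario 2 → 55,747 / 0.17 = 327,923.5 → 327,924;
    scenario 4 → 55,747 / 0.49 = 113,769.4 → 113,769; scenarios 1 and 3
    have negative per-user margins → infeasible.
    """
    if fixed_excl_promo <= 0:
        raise ValueError("fixed_excl_promo must be > 0")
    m = _margin(spec, traffic, promo_per_user)
    if m <= 0:
        return BreakevenResult(False, None, m)
    return BreakevenResult(True, int(math.floor(fixed_excl_promo / m + 0.5)), m)


def breakeven_volume_numeric(
    spec: ScenarioSpec,
    traffic: TrafficProfile,
    fixed_excl_promo: float,
    promo_per_user: float,
) -> BreakevenResult:
    """Break-even volume by bisection on ``net(U) = 0`` over [0, 1e9].

    Independent of the closed form (it only evaluates the net function);
    agrees with :func:`breakeven_volume` within one user wherever feasible.
    No sign change in the bracket means the net never reaches zero →
    infeasible.
    """
    if fixed_excl_promo <= 0:
        raise ValueError("fixed_excl_promo must be > 0")

    def net(users: float) -> float:
        t = TrafficProfile(
            traffic.sms_sent_per_user, traffic.sms_received_per_user, users
        )
        return net_at_volume(spec, t, fixed_excl_promo, promo_per_user).net_usd

    m = _margin(spec, traffic, promo_per_user)
    if net(0.0) * net(_BRACKET_MAX) > 0:  # net(0) = -F0 < 0 always
        return BreakevenResult(False, None, m)
    root = bisect(net, 0.0, _BRACKET_MAX, xtol=1e-4)
    return BreakevenResult(True, int(math.floor(root + 0.5)), m)
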