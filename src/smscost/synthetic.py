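"""Synthetic per-user SMS interaction logs, perturbed ledgers, and the
packaged 2014 m4RH Tanzania baseline inputs.

The service is query–response: a user texts a menu code and the system
replies with one to three SMS depending on content length.  The generator
emulates a year of such interactions — per-user query counts from a Poisson
law floored at one (a "user" has texted at least once), each query drawing
an independent 1–3 response count — so the whole pipeline (aggregation →
scenarios → break-even → Monte Carlo) is exercisable without any program
records.  The 2014 defaults (mean 8 queries, all-three responses) reproduce
the observed aggregates: 8 sent, 24 received, a 1:3 sent:received ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cost_ledger import CostLedger, TrafficProfile, read_ledger
from .scenarios import ScenarioSpec, scenario_presets
from .uncertainty import UncertaintyConfig

__all__ = [
    "InteractionLog",
    "generate_log",
    "aggregate_traffic",
    "perturbed_ledger",
    "m4rh_2014",
    "read_log_csv",
]

#: Default per-query response distribution: every query yields 3 replies —
#: the only {1,2,3}-supported distribution matching the observed mean of
#: 3 responses per query.  Alternative mixes are for robustness tests.
DEFAULT_RESPONSE_PROBS = {3: 1.0}


@dataclass(frozen=True)
class InteractionLog:
    """Per-user annual counts: queries sent and responses received.

    Invariant: ``responses_received <= 3 * queries_sent`` (at most three
    replies per query) and all counts are non-negative.
    """

    records: pd.DataFrame  # columns: user_id, queries_sent, responses_received

    def __post_init__(self) -> None:
        df = self.records
        required = {"user_id", "queries_sent", "responses_received"}
        if not required.issubset(df.columns):
            raise ValueError(f"log needs columns {sorted(required)}")
        if (df[["queries_sent", "responses_received"]] < 0).any().any():
            raise ValueError("counts must be >= 0")
        if (df["responses_received"] > 3 * df["queries_sent"]).any():
            raise ValueError("a query yields at most three responses")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def read_log_csv(path: str | Path) -> InteractionLog:
    return InteractionLog(pd.read_csv(path))


def generate_log(
    n_users: int,
    mean_queries: float = 8.0,
    response_probs: dict[int, float] | None = None,
    seed: int = 0,
) -> InteractionLog:
    """Draw a synthetic annual interaction log for ``n_users`` users.

    Queries per user are Poisson(``mean_queries``) floored at 1; each query
    independently yields 1–3 responses with probabilities
    ``response_probs`` (default: always 3).  Fully seeded.
    """
    if mean_queries <= 0:
        raise ValueError("mean_queries must be > 0")
    probs = DEFAULT_RESPONSE_PROBS if response_probs is None else response_probs
    if set(probs) - {1, 2, 3}:
        raise ValueError("response counts must be in {1, 2, 3}")
    p = np.array([probs.get(k, 0.0) for k in (1, 2, 3)], dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("response_probs must be a distribution over {1,2,3}")

    rng = np.random.default_rng(seed)
    queries = np.maximum(rng.poisson(mean_queries, n_users), 1)
    # one categorical draw per query, summed per user
    owner = np.repeat(np.arange(n_users), queries)
    per_query = rng.choice([1, 2, 3], size=owner.size, p=p)
    responses = np.bincount(owner, weights=per_query, minlength=n_users).astype(int)

    return InteractionLog(
        pd.DataFrame(
            {
                "user_id": np.arange(n_users),
                "queries_sent": queries,
                "responses_received": responses,
            }
        )
    )


def aggregate_traffic(log: InteractionLog, round_counts: bool = True) -> TrafficProfile:
    """Collapse a log to a traffic profile: user count and per-user mean
    sent/received (rounded to whole SMS by default, as reported figures
    are)."""
    if len(log) == 0:
        raise ValueError("cannot aggregate an empty log")
    sent = float(log.records["queries_sent"].mean())
    received = float(log.records["responses_received"].mean())
    if round_counts:
        sent, received = round(sent), round(received)
    return TrafficProfile(sent, received, len(log))


def perturbed_ledger(
    ledger: CostLedger, rel_sd: float = 0.1, seed: int = 0
) -> CostLedger:
    """A copy of ``ledger`` with every amount (and the SMS unit cost)
    jittered by a truncated-at-zero normal factor of relative sd
    ``rel_sd`` — for robustness tests of the downstream analyses."""
    rng = np.random.default_rng(seed)

    def jitter(x: float) -> float:
        return float(max(x * rng.normal(1.0, rel_sd), 0.0))

    items = tuple(
        it if it.annual_amount is None else replace(it, annual_amount=jitter(it.annual_amount))
        for it in ledger.items
    )
    return CostLedger(items, jitter(ledger.sms_unit_cost))


def m4rh_2014() -> tuple[
    CostLedger, TrafficProfile, dict[str, ScenarioSpec], UncertaintyConfig
]:
    """The exact 2014 baseline inputs, loaded from the packaged ledger file.

    Returns the cost ledger (fixed categories 21,000 / 23,040 / 11,707 /
    19,400; SMS unit cost 0.032), the traffic profile (8 sent, 24 received,
    125,320 users), the four scenario presets, and the default uncertainty
    configuration.
    """
    with resources.as_file(
        resources.files("smscost.data").joinpath("ledger_2014.yaml")
    ) as path:
        ledger = read_ledger(path)
    traffic = TrafficProfile(8, 24, 125_320)
    return ledger, traffic, scenario_presets(), UncertaintyConfig()
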