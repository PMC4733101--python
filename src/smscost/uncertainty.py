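"""Monte Carlo uncertainty analysis of the scenario net outcomes.

One year of program data pins down only point values for the three inputs
that drive the net outcome, so each is given a distribution and propagated
through the net-at-volume model:

* promotional cost per user — normal(mean $0.15, sd $0.02);
* SMS traffic per user — normal(mean 32, sd 2), split 1:3 into
  sent:received, the observed ratio;
* user volume — lognormal (user counts are positively skewed), with the
  arithmetic mean held at 125,320; the sd on the natural scale defaults to
  25,000 (~20% CV).  The lognormal is moment-matched: ``sigma^2 =
  ln(1 + (sd/mean)^2)``, ``mu = ln(mean) - sigma^2/2``, so the sample
  arithmetic mean equals the specified mean.

Negative normal draws are truncated at zero.  Each trial recomputes the
per-user SMS net with the drawn traffic and evaluates the net at the drawn
volume; trials are summarised by mean, 5th/95th percentiles (linear
interpolation), their spread, and the fraction of trials that break even
(net >= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cost_ledger import TrafficProfile
from .scenarios import ScenarioSpec, per_user_sms_net

__all__ = [
    "UncertaintyConfig",
    "SimulationSummary",
    "lognormal_params_from_moments",
    "simulate_net_trials",
    "run_monte_carlo",
    "summarize_trials",
]


@dataclass(frozen=True)
class UncertaintyConfig:
    """Input distributions and trial count for the Monte Carlo run."""

    promo_mean: float = 0.15  # USD/user
    promo_sd: float = 0.02
    sms_mean: float = 32.0  # SMS/user (sent + received)
    sms_sd: float = 2.0
    users_mean: float = 125_320.0
    users_sd: float = 25_000.0  # natural-scale sd of the lognormal volume
    sent_fraction: float = 0.25  # 1:3 sent:received split of drawn traffic
    n_trials: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.promo_sd, self.sms_sd, self.users_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.users_mean <= 0:
            raise ValueError("users_mean must be > 0")

    def with_seed(self, seed: int) -> "UncertaintyConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulationSummary:
    """Percentile summary of simulated annual nets (USD, full precision)."""

    label: str
    mean_net: float
    p5: float
    p95: float
    spread: float  # p95 - p5
    prob_breakeven: float  # fraction of trials with net >= 0
    n_trials: int


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with the given arithmetic
    mean and sd.  sd = 0 degenerates to a point mass at ``mean``."""
    if mean <= 0:
        raise ValueError("lognormal mean must be > 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_net_trials(
    spec: ScenarioSpec,
    config: UncertaintyConfig,
    fixed_excl_promo: float,
) -> np.ndarray:
    """Per-trial annual nets (USD) for one scenario.

    Seeded by ``config.seed``; identical configs give bit-identical trials.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials

    promo = np.maximum(rng.normal(config.promo_mean, config.promo_sd, n), 0.0)
    sms_total = np.maximum(rng.normal(config.sms_mean, config.sms_sd, n), 0.0)
    mu, sigma = lognormal_params_from_moments(config.users_mean, config.users_sd)
    users = np.exp(rng.normal(mu, sigma, n))

    sent = config.sent_fraction * sms_total
    received = sms_total - sent
    # per_user_sms_net is linear in (sent, received): evaluate via unit rates
    a = per_user_sms_net(spec, TrafficProfile(1.0, 0.0, 0.0))
    b = per_user_sms_net(spec, TrafficProfile(0.0, 1.0, 0.0))
    pun = a * sent + b * received
    return users * (pun - promo) - fixed_excl_promo


def summarize_trials(nets, label: str = "") -> SimulationSummary:
    """Mean, 5th/95th percentiles (linear interpolation between order
    statistics), spread, and break-even probability of a trial sequence."""
    arr = np.asarray(nets, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty trial sequence")
    p5, p95 = np.percentile(arr, [5, 95])
    return SimulationSummary(
        label=label,
        mean_net=float(arr.mean()),
        p5=float(p5),
        p95=float(p95),
        spread=float(p95 - p5),
        prob_breakeven=float(np.mean(arr >= 0.0)),
        n_trials=arr.size,
    )


def run_monte_carlo(
    spec: ScenarioSpec,
    config: UncertaintyConfig,
    fixed_excl_promo: float,
) -> SimulationSummary:
    """Simulate ``config.n_trials`` annual nets for ``spec`` and summarise.

    Because the net is affine in each independent input, the mean converges
    to the deterministic net at the input means (truncation effects are
    negligible at these coefficients of variation).
    """
    nets = simulate_net_trials(spec, config, fixed_excl_promo)
    return summarize_trials(nets, label=spec.label)
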