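"""Report emission: the cost table, the scenario/break-even table, and the
Monte Carlo summary table, as CSV with a provenance header.

Every output starts with comment lines recording the package version, the
seed, and a hash of the run configuration, so a file can be traced back to
the run that produced it; re-running the same configuration yields a
byte-identical file.  Display columns use whole dollars with thousands
separators; numeric columns keep full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cost_ledger import (
    CostLedger,
    TrafficProfile,
    promo_cost_per_user,
    read_ledger,
    round_usd,
    total_fixed_cost,
    total_program_cost,
    total_variable_cost,
)
from .breakeven import breakeven_volume
from .scenarios import (
    SCENARIOS,
    net_at_volume,
    reduction_vs_baseline,
    scenario_presets,
)
from .synthetic import m4rh_2014
from .uncertainty import UncertaintyConfig, run_monte_carlo

__all__ = ["RunConfig", "cmd_costs", "cmd_scenarios", "cmd_simulate", "usd"]


def usd(x: float) -> str:
    """Whole-dollar display with thousands separators, sign preserved."""
    return f"{round_usd(x):,}"


@dataclass(frozen=True)
class RunConfig:
    """Inputs for one reporting run.

    ``ledger_path`` of None means the packaged 2014 ledger; traffic
    defaults to the 2014 profile.  ``replication_mode`` swaps scenario 1
    for its published-figure variant (see :mod:`smscost.scenarios`).
    """

    ledger_path: str | None = None
    scenario_labels: tuple[str, ...] = tuple(SCENARIOS)
    traffic: TrafficProfile | None = None
    uncertainty: UncertaintyConfig = field(default_factory=UncertaintyConfig)
    out_dir: str = "."
    seed: int = 0
    replication_mode: bool = False

    def resolve(self) -> tuple[CostLedger, TrafficProfile]:
        ledger_2014, traffic_2014, _, _ = m4rh_2014()
        ledger = (
            read_ledger(self.ledger_path) if self.ledger_path else ledger_2014
        )
        return ledger, self.traffic or traffic_2014

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, config: RunConfig, name: str) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    buf = io.StringIO()
    buf.write(f"# smscost {__version__} seed={config.seed} config={config.digest()}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def cmd_costs(config: RunConfig) -> Path:
    """Emit the annual cost table: one row per ledger item plus fixed,
    variable and grand totals (2014 fixture: 75,147 / 128,328 / 203,475)."""
    ledger, traffic = config.resolve()
    rows = [
        {
            "section": "fixed",
            "category": it.category,
            "item": it.name,
            "amount": it.annual_amount,
            "display": usd(it.annual_amount),
        }
        for it in ledger.fixed_items
    ]
    var = total_variable_cost(ledger, traffic)
    if ledger.sms_unit_cost > 0 and traffic.users > 0:
        rows.append(
            {
                "section": "variable",
                "category": "sms",
                "item": f"SMS costs ({ledger.sms_unit_cost:g}/SMS x "
                f"{traffic.sms_total_per_user:g} SMS/user x {traffic.users:g} users)",
                "amount": var,
                "display": usd(var),
            }
        )
    for label, value in (
        ("Annual Fixed Costs", total_fixed_cost(ledger)),
        ("Annual Variable Costs", var),
        ("Total Program Costs", total_program_cost(ledger, traffic)),
    ):
        rows.append(
            {"section": "total", "category": "", "item": label,
             "amount": value, "display": usd(value)}
        )
    return _write(pd.DataFrame(rows), config, "costs.csv")


def cmd_scenarios(config: RunConfig) -> Path:
    """Emit the scenario table: net at the given volume, break-even volume
    (or "Not possible"), average user cost and reduction vs baseline."""
    ledger, traffic = config.resolve()
    presets = scenario_presets(config.replication_mode)
    baseline = total_program_cost(ledger, traffic)
    f0 = ledger.fixed_excl_promo
    promo = promo_cost_per_user(ledger, traffic)

    rows = []
    for label in config.scenario_labels:
        if label not in presets:
            raise KeyError(f"unknown scenario {label!r}")
        spec = presets[label]
        outcome = net_at_volume(spec, traffic, f0, promo)
        be = breakeven_volume(spec, traffic, f0, promo)
        rows.append(
            {
                "scenario": spec.label,
                "cost_to_user_per_sms": spec.user_price,
                "cost_to_program_per_sms": spec.program_rate,
                "user_pays_received": spec.user_pays_received,
                "net_at_volume": round_usd(outcome.net_usd),
                "net_display": usd(outcome.net_usd),
                "breakeven_users": be.volume if be.feasible else "Not possible",
                "avg_user_cost": outcome.avg_user_cost,
                "reduction_vs_baseline_pct": round(
                    100 * reduction_vs_baseline(outcome.net_usd, baseline)
                ),
            }
        )
    return _write(pd.DataFrame(rows), config, "scenarios.csv")


def cmd_simulate(config: RunConfig) -> Path:
    """Emit the Monte Carlo summary table: mean net, 5th/95th percentiles,
    their spread, and % of trials breaking even, per scenario.

    In replication mode scenario 1 is simulated with the published-figure
    variant, and the canonical scenario 1 is reported alongside, labeled.
    """
    ledger, traffic = config.resolve()
    f0 = ledger.fixed_excl_promo
    ucfg = dataclasses.replace(config.uncertainty, seed=config.seed)
    presets = scenario_presets(config.replication_mode)

    specs = [presets[label] for label in config.scenario_labels]
    if config.replication_mode and "scenario1" in config.scenario_labels:
        canonical = dataclasses.replace(SCENARIOS["scenario1"], label="scenario1-canonical")
        specs.append(canonical)

    rows = []
    for spec in specs:
        s = run_monte_carlo(spec, ucfg, f0)
        rows.append(
            {
                "scenario": spec.label,
                "mean_net": s.mean_net,
                "mean_display": usd(s.mean_net),
                "p5": s.p5,
                "p95": s.p95,
                "spread": s.spread,
                "pct_breakeven": 100 * s.prob_breakeven,
                "n_trials": s.n_trials,
                "seed": ucfg.seed,
                "sigma_users": ucfg.users_sd,
            }
        )
    return _write(pd.DataFrame(rows), config, "simulation.csv")
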