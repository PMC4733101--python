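# Methods

## The cost model

The unit of analysis is one program-year of an on-demand SMS health
service. Costs decompose into:

* **Fixed** — annual amounts independent of volume, stored as category
  totals: technology $21,000, administration $23,040, personnel $11,707,
  promotion $19,400 (2014 baseline, total $75,147). Category totals are
  authoritative and never recomputed from finer sub-lines; the published
  personnel sub-lines sum to $11,705 while the category total is $11,707,
  and only the category totals keep every downstream figure consistent
  with the $75,147 fixed total.
* **Variable** — SMS delivery: `unit cost × SMS per user × users`. The
  2014 baseline rate is $0.032/SMS; with 32 SMS/user and 125,320 users
  this gives $128,327.68, reported as $128,328. Annual traffic is modeled
  as 32 × users = 4,010,240 SMS. (The separately reported annual total of
  4,057,190 SMS implies users averaged slightly more than 32; the cost
  arithmetic is consistent only with 32 × users, so that is what the model
  uses.)

The baseline delivery rate ($0.032) and the scenario rates
($0.03/$0.02/$0.01) are distinct fields and never conflated. All internal
arithmetic is full floating precision; rounding — whole dollars, halves
away from zero — happens only in reports.

## Scenarios

A `ScenarioSpec` is (user price *p*, program bulk rate *c*, does the user
pay for received SMS). The canonical accounting is: the program earns the
margin *m = p − c* on every user-paid SMS and pays *c* to deliver every SMS
the user does not pay for. Four presets span bulk rates of $0.02
(scenarios 1–2) and $0.01 (3–4) crossed with sent-only (1, 3) versus
pay-for-all (2, 4), all at *p* = $0.03.

In both outcome analyses promotion is a **variable** cost of exactly
$0.15/user — the two-decimal value of 19,400 / 125,320 = 0.1548, carried
at $0.15 because the break-even volumes are reproducible only with that
figure. The fixed-volume nets equally imply it: the effective fixed cost
behind the published nets is 55,747 + 0.15 × 125,320 = 74,545.4, not
75,147. The remaining fixed cost is F₀ = $55,747 and

    net(U) = U · (net/user − 0.15) − F₀.

**Replication variant.** The published scenario-1 figures (net −$94,596;
user costs $0.16 and $0.64 for scenarios 1–2) are arithmetically
inconsistent with that scenario's stated $0.02 bulk rate: they follow only
if both the delivery rate and the user-side price sit one tier lower
($0.01 delivery, $0.02 price). Rather than silently mixing conventions,
the package keeps a single coherent canonical model (which reproduces the
scenario 2–4 nets, both break-even volumes and the scenario 3–4 user
costs) and exposes the published variant explicitly as
`SCENARIO_1_REPLICATION` / `net_at_volume_replication_s1`. That variant is
the canonical formula at (p, c) = (0.02, 0.01) sent-only, which reproduces
both the printed net and the printed $0.16 user cost; reporting uses it
only when `replication_mode` is switched on (default off), with the
canonical scenario 1 labeled alongside in Monte Carlo output.

Average user cost is `price × number of SMS the user pays for` — $0.24
sent-only, $0.96 pay-for-all at $0.03. Cost *reduction* versus the
donor-funded baseline is `1 − |net| / 203,475` for a shortfall, and full
(1.0) for any profit.

## Break-even

Because net(U) is affine, the break-even volume is the closed form
`U* = F₀ / (net/user − promo/user)` whenever the per-user margin is
positive; otherwise the shortfall grows with volume and the result is a
typed infeasibility ("Not possible"), not an exception. U\* is rounded to
the **nearest** whole user: ceiling would guarantee net ≥ 0 but fails the
published 113,769 (113,769.4 would become 113,770); nearest reproduces
both published volumes (327,923.5 → 327,924; 113,769.4 → 113,769). An
independent numeric solver (bisection on net(U) = 0 over [0, 10⁹],
xtol 10⁻⁴) cross-checks the closed form; they agree within one user over
randomized parameter draws.

## Monte Carlo uncertainty analysis

One program-year pins down only point values, so the three volume-linked
inputs get distributions and 10,000 trials propagate them through net(U):

| input | distribution | default | why |
|---|---|---|---|
| promotion cost/user (USD) | normal, truncated at 0 | mean 0.15, sd 0.02 | stated year-to-year variability |
| SMS per user | normal, truncated at 0 | mean 32, sd 2 | stated variability; split 1:3 sent:received |
| user volume | lognormal, moment-matched | mean 125,320, sd 25,000 | user counts are positively skewed |

Choices the inputs do not fully determine:

* **σ_U = 25,000** (≈20% CV). The user-volume sd is not stated anywhere;
  25,000 is a calibration chosen so the simulated 5th–95th spreads
  approximate the published per-scenario spreads ($18,027–$42,453), and it
  is an explicit config knob (`users_sd`). Consequently the exact
  percentile values and the 62% scenario-4 break-even probability are
  calibration-sensitive; tests hold the spreads to ±30% of the published
  ranges rather than asserting them exactly.
* **Lognormal parameterization** by moment matching —
  σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2 — so the *arithmetic*
  sample mean equals the specified mean.
* **Traffic split**: a drawn per-user total t is allocated sent = t/4,
  received = 3t/4, preserving the observed 1:3 ratio (the split itself has
  no stated distribution).
* **Truncation at 0** for the normal draws: resampling would bias the
  mean upward; truncation is measurable and negligible at these CVs
  (0.15/0.02 is 7.5 sd from zero, 32/2 is 16 sd).
* **Percentiles** by linear interpolation between order statistics
  (numpy's default); spread = p95 − p5; break-even probability counts
  trials with net ≥ 0.

Because net is affine in each independent input, the trial mean converges
to the deterministic net at the input means; at 10,000 trials the standard
error is ≈$135 for scenario 4, so simulated means sit within a few hundred
dollars of the $5,660 analytic value (and of the published $5,457). For
any scenario whose per-user margin is negative for every admissible draw
(sent-only scenarios at these rates), no trial can break even, so the 0%
rows are structural, not sampling accidents.

## Synthetic interaction logs

The generator emulates a year of query–response traffic: per-user query
counts Poisson(mean 8) floored at 1 (a "user" has texted at least once),
each query independently yielding 1–3 reply SMS. The default response
distribution is all-3 — the only distribution supported on {1, 2, 3} whose
mean matches the observed 3 replies per query; mixed distributions are
options for robustness tests. Aggregating a large generated cohort
recovers the 8 sent / 24 received / 1:3 profile within sampling error, and
`perturbed_ledger` jitters ledger amounts (truncated-normal factors) for
downstream robustness checks.

What the generator does **not** emulate: within-year timing, message
content, churn, heavy-tailed per-user usage, or correlation between
promotion spend and volume. Passing tests therefore show the pipeline is
internally consistent with the stated aggregates, not that real usage data
would follow these shapes.

## Numerical and reporting conventions

* Whole-dollar rounding, halves away from zero, at report time only;
  display columns add thousands separators, machine columns keep full
  precision.
* Zero users makes cost-per-user and promotion-per-user undefined
  (raised), leaves the fixed cost as the net shortfall, and zero margin
  makes break-even infeasible rather than a division error.
* Every report file header records package version, seed and a
  configuration hash; identical configurations produce byte-identical
  files, and a fixed seed makes the simulator bit-reproducible.
* Test and acceptance problem sizes: 10,000 Monte Carlo trials (the
  analysis default), 10⁵-user synthetic cohorts for convergence checks,
  1,000 random draws for the solver cross-check — all chosen to make
  sampling error small relative to the asserted tolerances.

## Known limitations

* Single-year, single-currency (2014 USD) snapshot: no discounting,
  projection, or TZS↔USD conversion.
* Promotion-proportional-to-volume is an assumption, not an estimate; if
  promotion is partly fixed, break-even volumes shift.
* The willingness-to-pay side (whether users *would* pay $0.24–$0.96 a
  year) is outside the model.
* Revenue-sharing with aggregators, tiered/subscription pricing and
  advertising revenue are not modeled.
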