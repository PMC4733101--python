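# smscost

Cost-recovery, break-even and uncertainty modeling for SMS health services
operating at national scale.

Many mHealth programs in low-resource settings are donor-funded and stall
when funding ends. `smscost` packages the financial model of one such
service — m4RH Tanzania, an on-demand SMS family-planning information
service that in 2014 reached 125,320 users at a total annual cost of
$203,475 — and makes its sustainability analysis reusable and testable:
for program implementers, health economists and analysts asking *"at what
price structure and user volume does an SMS service pay for itself?"*

## The model

Annual cost splits into a fixed part F (technology, administration,
personnel, promotion) and a variable part proportional to SMS traffic
(unit cost × SMS per user × users). A pay-for-service scenario sets a user
price *p* per SMS (held at the standard $0.03 rate), a negotiated bulk rate
*c* the program pays the operator, and whether users pay only for the *s*
messages they send or also for the *r* they receive. The program earns the
margin *m = p − c* on every user-paid SMS and pays *c* to deliver the rest,
so per user

    net/user = m·(s + r)            (user pays all)
    net/user = m·s − c·r            (user pays sent only)

Promotion is treated as a variable cost of $0.15 per user (it is assumed to
drive volume), leaving F₀ = $55,747 of fixed cost, and the annual net at a
volume U is affine:

    net(U) = U · (net/user − promo/user) − F₀

Break-even is the root U\* = F₀ / (net/user − promo/user) when the per-user
margin is positive, and infeasible otherwise. A 10,000-trial Monte Carlo
propagates uncertainty in promotion cost/user ~ N(0.15, 0.02), SMS
traffic/user ~ N(32, 2), and user volume ~ lognormal (moment-matched, mean
125,320, sd 25,000) through net(U). See `docs/methods.md` for assumptions,
parameter choices and the published-figure replication variant of
scenario 1.

## Worked example

```sh
smscost --seed 42 --out demo scenario
```

writes `demo/scenarios.csv`:

```
scenario,cost_to_user_per_sms,cost_to_program_per_sms,user_pays_received,net_at_volume,net_display,breakeven_users,avg_user_cost,reduction_vs_baseline_pct
scenario1,0.03,0.02,False,-124673,"-124,673",Not possible,0.24,39
scenario2,0.03,0.02,True,-34443,"-34,443",327924,0.96,83
scenario3,0.03,0.01,False,-84571,"-84,571",Not possible,0.24,58
scenario4,0.03,0.01,True,5660,"5,660",113769,0.96,100
```

Reading scenario 4 (bulk rate $0.01, users pay for all 32 SMS): at the 2014
volume the program clears a $5,660 annual profit, needs 113,769 users to
break even, and costs each user $0.96 a year. Scenario 2 falls $34,443
short — an 83% reduction from the $203,475 donor-funded baseline — and
would break even at 327,924 users; the sent-only scenarios 1 and 3 have
negative per-user margins, so no volume breaks even. The same numbers are
available in the library:

```python
from smscost import m4rh_2014, net_at_volume, breakeven_volume, promo_cost_per_user

ledger, traffic, presets, ucfg = m4rh_2014()
promo = promo_cost_per_user(ledger, traffic)   # 0.15
out = net_at_volume(presets["scenario4"], traffic, ledger.fixed_excl_promo, promo)
out.net_usd                                    # 5659.8
breakeven_volume(presets["scenario4"], traffic, ledger.fixed_excl_promo, promo).volume
                                               # 113769
```

`smscost breakeven --scenario scenario4` prints the margin decomposition:

```
scenario4: break-even volume = 113,769
  per-user SMS net +0.64  - promo/user 0.15  = margin +0.49 USD/user;  fixed excl. promo 55,747
```

and `smscost --seed 42 simulate` writes the Monte Carlo table — e.g.
scenario 4: mean net $5,967 (vs the $5,660 analytic value, within Monte
Carlo error), a 5th–95th percentile spread of about $44,379, and 63.8% of
trials breaking even.

Other subcommands: `costs` (the annual cost table), `synth` (a synthetic
per-user interaction log for end-to-end runs without program records).
Global flags `--config`, `--seed`, `--out`, `--replication-mode`; an
example configuration ships as `src/smscost/data/config_2014.yaml`.

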