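# Example run configuration: the 2014 baseline analysis.
# `ledger: null` means the packaged 2014 ledger.
ledger: null
scenarios: [scenario1, scenario2, scenario3, scenario4]
traffic:
  sent: 8
  received: 24
  users: 125320
uncertainty:
  promo_mean: 0.15
  promo_sd: 0.02
  sms_mean: 32.0
  sms_sd: 2.0
  users_mean: 125320.0
  users_sd: 25000.0
  n_trials: 10000
seed: 0
replication_mode: false
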