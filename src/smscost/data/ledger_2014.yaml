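fixed:
  technology:
    Technology costs: 21000
  administration:
    Administration costs: 23040
  personnel:
    Personnel costs: 11707
  promotion:
    Promotional costs: 19400
variable:
  sms_unit_cost: 0.032
  sms_item: SMS costs
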