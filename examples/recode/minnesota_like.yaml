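# Example recode config for a cohort with graded frequency responses
# binarized at any regular use / any use.
- item_name: cigarettes_per_day_regular
  trait: rsi
  response_map: {"never": 0, "less_than_daily": 1, "daily": 1}
  skipout_fill: 0
- item_name: times_used_cannabis
  trait: ci
  response_map: {"0": 0, "1-5": 1, "6-20": 1, "21+": 1}
  skipout_fill: 0
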