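# Example recode config for a two-cohort register where one cohort's
# item conflates cannabis with other drugs: an affirmative answer on
# the combined item is coded as cannabis initiation.
- item_name: smoked_100_cigarettes
  trait: rsi
  response_map: {"yes": 1, "no": 0}
- item_name: ever_used_cannabis
  trait: ci
  response_map: {"yes": 1, "no": 0}
- item_name: ever_used_cannabis_or_other_drugs
  trait: ci
  combined_item: true
  response_map: {"yes": 1, "no": 0}
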