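# Example recode config for a register whose smoking block asks about
# regular smoking directly and whose cannabis item is cannabis-only.
# Illustrative item wordings and codes; real questionnaires differ.
- item_name: ever_smoked_regularly
  trait: rsi
  response_map: {"yes": 1, "no": 0}
  skipout_fill: 0          # never-smokers skip the regular-smoking item
- item_name: ever_used_cannabis
  trait: ci
  response_map: {"yes": 1, "no": 0}
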