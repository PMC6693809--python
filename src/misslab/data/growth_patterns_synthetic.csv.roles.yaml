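columns:
  birth_weight:
    type: continuous
    role: confounder
  sex:
    type: binary
    role: confounder
  gestational_age:
    type: categorical
    role: confounder
    levels:
    - <39
    - 39-40
    - '>41'
  maternal_weight:
    type: continuous
    role: confounder
  paternal_weight:
    type: continuous
    role: confounder
  ses:
    type: categorical
    role: confounder
    levels:
    - I/II
    - III
    - IV/V
  weight_5:
    type: continuous
    role: exposure
  adult_bmi:
    type: continuous
    role: outcome
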