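{
 "name": "composite_lifestyle",
 "perturbations": [
  {"variable": "physical_activity", "kind": "ordinal_shift", "value": 1},
  {"variable": "current_smoker", "kind": "categorical_set", "value": 0},
  {"variable": "alcohol_drinks_week", "kind": "additive", "value": -2.0},
  {"variable": "anxiety_score", "kind": "multiplicative", "value": -0.20},
  {"variable": "depression_score", "kind": "multiplicative", "value": -0.20}
 ],
 "propagate": []
}
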