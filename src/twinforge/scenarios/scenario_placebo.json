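{
 "name": "placebo_weight_0pct",
 "perturbations": [
  {"variable": "weight_lbs", "kind": "multiplicative", "value": 0.0}
 ],
 "propagate": [["weight_lbs", "bmi"]]
}
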