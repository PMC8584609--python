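{
  "name": "published-multinomial",
  "coefficients": {
    "approach": 1.957,
    "crp_preop_mean": 0.0041,
    "crp_max_day": 0.611,
    "sex": -18.57,
    "failure_to_decline_d4": 1.965
  },
  "intercept": 4.988,
  "cutoff": -8.566
}
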