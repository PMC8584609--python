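{
  "name": "published-binary",
  "coefficients": {
    "second_peak": -2.447,
    "crp_max": 0.004,
    "bmi": 0.029,
    "sex": -1.504,
    "crp_max_day": 0.381,
    "crp_preop_mean": 0.024
  },
  "intercept": -5.85,
  "cutoff": -4.725
}
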