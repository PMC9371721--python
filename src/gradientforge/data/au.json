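{
  "name": "Au",
  "dD_um": 50.0,
  "channels": [
    {"i0_A_per_m2": 2.0e-8, "n_rds": 1.0, "n_stoich": 4, "alpha_c": 0.5},
    {"i0_A_per_m2": 8.0e-7, "n_rds": 0.7, "n_stoich": 2, "alpha_c": 0.5}
  ]
}
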