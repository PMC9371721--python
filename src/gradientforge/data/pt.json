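{
  "name": "Pt",
  "dD_um": 20.0,
  "channels": [
    {"i0_A_per_m2": 3.0e-6, "n_rds": 1.0, "n_stoich": 4, "alpha_c": 0.5}
  ]
}
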