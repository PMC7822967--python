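{
  "tau_ca_ms": 22.4,
  "p_max_vm": 0.91,
  "k_half": 0.68,
  "k_min_per_ms": 0.0012,
  "delta_k_per_ms": 0.0094,
  "k_r_half": 0.19,
  "delta_jump": 1.0,
  "label": "HC"
}
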