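{
  "tau_ca_ms": 27.7,
  "p_max_vm": 0.75,
  "k_half": 0.69,
  "k_min_per_ms": 0.0009,
  "delta_k_per_ms": 0.017,
  "k_r_half": 1.18,
  "delta_jump": 1.0,
  "label": "SH"
}
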