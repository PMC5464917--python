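{
  "breast_imrt_lung": {"n": 0.912, "m": 0.437, "td50_1_gy": 17.211},
  "emami_burman_lung": {"n": 0.87, "m": 0.18, "td50_1_gy": 24.5}
}
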