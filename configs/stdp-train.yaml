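# STDP training on the randomized 10-ratio pulse sequence
pipeline: stdp-train
seed: 1
stdp:
  dw_plus: 150.0
  dw_minus: 150.0
  tau_plus: 20.0
  tau_minus: 20.0
stimulus:
  pulse_ms: 100.0
  gap_ms: 100.0
  rc_tau_ms: 10.0
classify:
  epochs: 300
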