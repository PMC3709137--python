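# Five-ratio synthetic chemosensor classification: model output vs raw input
pipeline: ratiometric
seed: 1
sawr:
  trials_per_class: 10
  noise_sigma_hz: 10.0
classify:
  pool_size: 5
  n_times: 20
  compression_ms_per_s: 10.0
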