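# FPA vs LCA regime comparison (winner-switch statistics under a 1:2 pulse)
pipeline: regimes
seed: 1
network:
  n_ln: 30
  n_pn_per_glom: 15
  noise_sigma: 0.0125
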