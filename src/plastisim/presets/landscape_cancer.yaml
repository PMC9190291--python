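# Oncogenically lowered barrier: higher probability of a state transition.
module: landscape
landscape:
  barrier: 0.5
  diffusion: 0.4
  x_min: -2.0
  x_max: 2.0
  n_grid: 401
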