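# Phenotypic memory, slow s-decay / fast r-decay: micro-persister dynamics.
# Decay rates are slow/fast relative to each phenotype's division time
# (off-treatment S cells divide every ~3 steps). The population is driven
# to a handful of cells during each pulse, survives through the R rump
# replenished by the genotype leak, and regrows rapidly after treatment.
module: abm
abm:
  genotype: {g_s: 53, g_r: 47}
  memory_enabled: true
  decay_rate_s: 0.3
  decay_rate_r: 2.0
therapy:
  n_pulses: 6
  pulse_duration: 10.0
  inter_pulse_gap: 20.0
  start_time: 50.0
  kill_probability_S: 0.9
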