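# Phenotypic memory, S-biased genotype, slow decay of both species:
# hybrid growth. Therapy starts while the population is far below its
# (large) carrying capacity; after the first pulse the memory-locked
# resistant lineage carries monotone growth through the remaining pulses,
# and the population grows comparably on and off treatment.
module: abm
abm:
  genotype: {g_s: 57, g_r: 43}
  memory_enabled: true
  decay_rate_s: 0.01
  decay_rate_r: 0.01
  carrying_capacity: 50000
  horizon: 200.0
therapy:
  n_pulses: 6
  pulse_duration: 10.0
  inter_pulse_gap: 20.0
  start_time: 0.0
  kill_probability_S: 0.9
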