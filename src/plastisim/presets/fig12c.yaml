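# Phenotypic memory with decay rates swapped (fast s-decay, slow r-decay):
# tissue preservation. R memory compounds at the slow carrying-capacity
# churn, so the standing population is resistant-rich and therapy removes
# less than half of it. Longer pre-treatment equilibration and a slightly
# faster R division rate let the memory-driven composition establish.
module: abm
abm:
  genotype: {g_s: 53, g_r: 47}
  memory_enabled: true
  decay_rate_s: 0.5
  decay_rate_r: 0.01
  division_probability_R: 0.15
  baseline_death_probability: 0.03
  horizon: 500.0
therapy:
  n_pulses: 6
  pulse_duration: 10.0
  inter_pulse_gap: 20.0
  start_time: 250.0
  kill_probability_S: 0.9
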