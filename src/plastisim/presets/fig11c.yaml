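# Memoryless bet-hedging, S-biased genotype: persister dynamics.
# Deep kills at each drug pulse; the R subpopulation prevents extinction
# and the population regrows between and after pulses.
module: abm
abm:
  genotype: {g_s: 53, g_r: 47}
  memory_enabled: false
therapy:
  n_pulses: 6
  pulse_duration: 10.0
  inter_pulse_gap: 20.0
  start_time: 50.0
  kill_probability_S: 0.9
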