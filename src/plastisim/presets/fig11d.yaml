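# Memoryless bet-hedging, R-biased genotype: tissue-preservation dynamics.
# The mostly-resistant population stays near carrying capacity throughout
# therapy, at the cost of slow off-treatment growth.
module: abm
abm:
  genotype: {g_s: 46, g_r: 54}
  memory_enabled: false
therapy:
  n_pulses: 6
  pulse_duration: 10.0
  inter_pulse_gap: 20.0
  start_time: 50.0
  kill_probability_S: 0.9
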