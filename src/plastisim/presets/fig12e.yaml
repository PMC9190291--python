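# Phenotypic memory, strongly S-biased genotype, fast decay of both
# species: extinction. The resistant phenotype is produced too rarely
# (p_R about 1%) and erodes during pulses, so the pulse train drives the
# whole population extinct.
module: abm
abm:
  genotype: {g_s: 60, g_r: 40}
  memory_enabled: true
  decay_rate_s: 0.5
  decay_rate_r: 0.5
therapy:
  n_pulses: 6
  pulse_duration: 10.0
  inter_pulse_gap: 20.0
  start_time: 50.0
  kill_probability_S: 0.9
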