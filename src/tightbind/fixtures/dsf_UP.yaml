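# DSF melt of the unprocessed (covalent) propeptide-protease complex.
# Ramp 25->99 C at 0.05 C/s sampled every second (0.05 C grid).
# Truth Tm = 67.8 C; width and baselines are fixture choices.
name: dsf_UP
kind: dsf
ramp:
  t_start_C: 25.0
  t_end_C: 99.0
  rate_C_per_s: 0.05
  sample_every_s: 1.0
truth:
  tm_C: 67.8
  width_C: 1.5
baselines:
  native_intercept: 1000.0
  native_slope: 2.0
  unfolded_intercept: 9000.0
  unfolded_slope: -15.0
quench_tau_C: 6.0
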