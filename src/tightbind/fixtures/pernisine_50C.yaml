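# 50 C inhibition series, faster-association regime.  Truth: Ki' = 20 pM.
name: pernisine_50C
kind: progress
design:
  enzyme_nM: 2.0
  substrate_mM: 0.5
  temperature_C: 50.0
  duration_s: 900.0
  sampling_interval_s: 2.0
  extinction_M_cm: 8800.0
  path_length_cm: 1.0
  baseline: 0.05
  kcat_per_s: 25.0
  km_mM: 0.5
inhibitor_grid_nM: [0.0, 1.0, 2.0, 4.0, 8.0]
truth:
  ki_app_nM: 0.020
  kon_app_per_M_s: 1.0e+7
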