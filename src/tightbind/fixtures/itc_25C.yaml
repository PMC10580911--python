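# 25 C titration: 19 x 5 uL of 100 uM titrant into 5 uM protein.
# Truth n = 0.68, KD = 96 nM; dH = -50 kJ/mol is a fixture choice (only the
# exothermic sign is constrained).  c = n*M0/KD ~ 35: well conditioned.
name: itc_25C
kind: itc
design:
  cell_volume_uL: 950.0
  cell_conc_uM: 5.0
  syringe_conc_uM: 100.0
  n_injections: 19
  injection_volume_uL: 5.0
  temperature_C: 25.0
truth:
  n: 0.68
  kd_nM: 96.0
  delta_h_kJ_mol: -50.0
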