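# 50 C titration, same geometry.  Truth n = 0.89, KD = 1.3 nM.
# c ~ 3400: KD is weakly identified by construction (conditioning warning).
name: itc_50C
kind: itc
design:
  cell_volume_uL: 950.0
  cell_conc_uM: 5.0
  syringe_conc_uM: 100.0
  n_injections: 19
  injection_volume_uL: 5.0
  temperature_C: 50.0
truth:
  n: 0.89
  kd_nM: 1.3
  delta_h_kJ_mol: -50.0
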