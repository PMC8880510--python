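sim:
  n_patients: 296
  n_features: 164
  seed: 1
  planted:
    - variable: 0
      beta_dox: 0.6
      beta_doxevo: 0.0
target_arm: DOX
alpha: 0.05
make_plots: true
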