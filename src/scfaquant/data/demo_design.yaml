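# Demo run: 6-level calibration + 4 pseudoblanks + one 13C-labeled
# fermentation sample (acetate predominantly 13C2, butyrate an unlabeled /
# 13C2 mixture) measured against the default panel.
seed: 7
n_calibration_levels: 6
n_blanks: 4
labeled_analytes: [acetic acid, butyric acid]
samples:
  - sample_id: fermentation
    role: sample
    matrix_factor: 1.3
    totals: {acetic acid: 100.0, butyric acid: 40.0}
    fractions:
      acetic acid: {0: 0.2, 2: 0.8}
      butyric acid: {0: 0.5, 2: 0.5}
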