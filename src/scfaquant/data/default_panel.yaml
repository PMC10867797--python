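# Default acid panel: 18 gut-microbial carboxylic-acid metabolites and the
# three internal standards used to quantify them (d4-acetic acid for the
# short-chain acids, 2-ethylbutyric acid for the longer/branched chains,
# d2-indole-3-propionic acid for the indole derivatives).
#
# qualifier_rule: a number means a fixed product m/z; "water_loss" means
# precursor - H2O; "none" omits the qualifier. quantifier_mz overrides the
# default protonated-2-picolylamine product (m/z 109) where the optimized
# fragment differs. cal_range in ug/mL; CE in eV; RT in minutes.
panel:
  - name: acetic acid
    acid_formula: C2H4O2
    n_acid_carbons: 2
    rt_min: 1.15
    ce_quant: 14
    ce_qual: 10
    qualifier_rule: water_loss
    cal_range: [5, 500]
    internal_standard: d4-acetic acid
  - name: lactic acid
    acid_formula: C3H6O3
    n_acid_carbons: 3
    rt_min: 1.28
    ce_quant: 15
    ce_qual: 23
    qualifier_rule: 92
    cal_range: [2, 250]
    internal_standard: d4-acetic acid
  - name: propionic acid
    acid_formula: C3H6O2
    n_acid_carbons: 3
    rt_min: 1.85
    ce_quant: 15
    ce_qual: 23
    qualifier_rule: 92
    cal_range: [5, 500]
    internal_standard: d4-acetic acid
  - name: isobutyric acid
    acid_formula: C4H8O2
    n_acid_carbons: 4
    rt_min: 3.11
    ce_quant: 15
    ce_qual: 11
    qualifier_rule: water_loss
    cal_range: [0.05, 2.5]
    internal_standard: 2-ethylbutyric acid
  - name: succinic acid
    acid_formula: C4H6O4
    n_carboxyl: 2
    n_acid_carbons: 4
    rt_min: 3.26
    ce_quant: 16
    ce_qual: 12
    quantifier_mz: 191    # loss of one neutral 2-PA from the bis-amide
    qualifier_rule: 109
    cal_range: [0.8, 25]
    internal_standard: 2-ethylbutyric acid
  - name: butyric acid
    acid_formula: C4H8O2
    n_acid_carbons: 4
    rt_min: 3.32
    ce_quant: 15
    ce_qual: 23
    qualifier_rule: 92
    cal_range: [5, 500]
    internal_standard: d4-acetic acid
  - name: 2-methylbutyric acid
    acid_formula: C5H10O2
    n_acid_carbons: 5
    rt_min: 5.03
    ce_quant: 15
    ce_qual: 11
    qualifier_rule: water_loss
    cal_range: [0.05, 2.5]
    internal_standard: 2-ethylbutyric acid
  - name: isovaleric acid
    acid_formula: C5H10O2
    n_acid_carbons: 5
    rt_min: 5.50
    ce_quant: 15
    ce_qual: 11
    qualifier_rule: water_loss
    cal_range: [0.05, 2.5]
    internal_standard: 2-ethylbutyric acid
  - name: valeric acid
    acid_formula: C5H10O2
    n_acid_carbons: 5
    rt_min: 6.08
    ce_quant: 15
    ce_qual: 11
    qualifier_rule: water_loss
    cal_range: [0.16, 10]
    internal_standard: 2-ethylbutyric acid
  - name: 2,2-dimethylbutyric acid
    acid_formula: C6H12O2
    n_acid_carbons: 6
    rt_min: 8.10
    ce_quant: 16
    ce_qual: 28
    qualifier_rule: 92
    cal_range: [0.002, 0.1]
    internal_standard: 2-ethylbutyric acid
  - name: indole-3-acetic acid
    acid_formula: C10H9NO2
    n_acid_carbons: 10
    rt_min: 8.18
    ce_quant: 24
    qualifier_rule: none
    cal_range: [0.004, 0.5]
    internal_standard: d2-indole-3-propionic acid
  - name: indole-3-lactic acid
    acid_formula: C11H11NO3
    n_acid_carbons: 11
    rt_min: 8.23
    ce_quant: 20
    qualifier_rule: none
    cal_range: [0.004, 0.5]
    internal_standard: d2-indole-3-propionic acid
  - name: 2-methylvaleric acid
    acid_formula: C6H12O2
    n_acid_carbons: 6
    rt_min: 8.25
    ce_quant: 15
    qualifier_rule: none
    cal_range: [0.002, 0.1]
    internal_standard: 2-ethylbutyric acid
  - name: 3-methylvaleric acid
    acid_formula: C6H12O2
    n_acid_carbons: 6
    rt_min: 8.59
    ce_quant: 15
    qualifier_rule: none
    cal_range: [0.002, 0.1]
    internal_standard: 2-ethylbutyric acid
  - name: 4-methylvaleric acid
    acid_formula: C6H12O2
    n_acid_carbons: 6
    rt_min: 9.20
    ce_quant: 15
    qualifier_rule: none
    cal_range: [0.002, 0.1]
    internal_standard: 2-ethylbutyric acid
  - name: indole-3-propionic acid
    acid_formula: C11H11NO2
    n_acid_carbons: 11
    rt_min: 9.51
    ce_quant: 28
    ce_qual: 20
    quantifier_mz: 201    # pyridine loss from the derivative
    qualifier_rule: 109
    cal_range: [0.002, 0.1]
    internal_standard: d2-indole-3-propionic acid
  - name: caproic acid
    acid_formula: C6H12O2
    n_acid_carbons: 6
    rt_min: 9.88
    ce_quant: 15
    ce_qual: 15
    qualifier_rule: 99
    cal_range: [0.001, 1]
    internal_standard: 2-ethylbutyric acid
  - name: indole-3-butyric acid
    acid_formula: C12H13NO2
    n_acid_carbons: 12
    rt_min: 11.87
    ce_quant: 16
    qualifier_rule: none
    cal_range: [0.002, 0.1]
    internal_standard: d2-indole-3-propionic acid
  # ---- internal standards (spiked at fixed stock concentrations) --------
  - name: d4-acetic acid
    acid_formula: C2[2H]4O2       # CD3COOD; the carboxyl O-D is exchangeable
    n_acid_carbons: 2
    exchangeable_deuterium: 1
    rt_min: 1.11
    ce_quant: 14
    ce_qual: 18
    quantifier_mz: 110    # one deuterium retained in the 2-PA fragment
    qualifier_rule: 92
    is_stock_ugml: 100
  - name: 2-ethylbutyric acid
    acid_formula: C6H12O2
    n_acid_carbons: 6
    rt_min: 7.26
    ce_quant: 15
    ce_qual: 19
    qualifier_rule: 71
    is_stock_ugml: 10
  - name: d2-indole-3-propionic acid
    acid_formula: C11H9[2H]2NO2   # deuterium on the propionic chain, non-exchangeable
    n_acid_carbons: 11
    rt_min: 9.45
    ce_quant: 28
    ce_qual: 20
    quantifier_mz: 130
    qualifier_rule: 110
    is_stock_ugml: 50
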