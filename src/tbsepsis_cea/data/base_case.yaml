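# Base-case inputs for the HIV/TB-sepsis decision model (Ugandan cohort).
# Probabilities and diagnostic accuracies are given in percent, exactly as
# published; ranges appear where the source reported them for one-way
# sensitivity analysis.
probabilities:
  units: percent
  prevalence_tb: {value: 50}
  p_treatment_success_sensitive: {value: 80, low: 66, high: 92}
  p_resistance: {value: 6.5, low: 4, high: 15}
  p_death_treated_tb: {value: 13.5}
  p_death_untreated_tb: {value: 90, low: 75, high: 100}
  p_death_suspect_no_tb: {value: 20, low: 7, high: 30}
  # Uptake of delayed empiric anti-TB therapy among missed-TB patients who
  # survive the initial untreated period; defaults to day-7 survival of
  # non-confirmed TB suspects (1 - p_death_suspect_no_tb).
  p_delayed_empiric: {value: 80}
utilities:
  units: fraction
  dw_tb_hiv: {value: 0.399}
  dw_tb_treatment: {value: 0.1}
  dw_hiv_art: {value: 0.053}
  dw_severe_sepsis: {value: 0.31}
costs:
  cost_tb_treatment: {value: 195}
diagnostics:
  units: percent
  lam:
    name: urine TB-LAM
    sensitivity: 53
    specificity: 96
    unit_cost: 4.19
  xpert:
    name: sputum Xpert MTB/RIF
    sensitivity: 42
    specificity: 99
    unit_cost: 17.42
  combined:
    name: combined LAM+Xpert
    sensitivity: 63.5
    specificity: 99
    # both assays are performed: 4.19 + 17.42
    unit_cost: 21.61
horizon_years: 1.0
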