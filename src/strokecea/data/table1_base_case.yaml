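# Base-case model inputs for the comparison of endovascular treatment (EVT)
# alone versus EVT plus intravenous thrombolysis (IVT) in acute ischemic
# stroke. Probabilities are fractions; monetary values are 2023 RMB.

arms:
  evt:
    label: "EVT alone"
    mrs_3m: {good: 0.4900, poor: 0.3519, dead: 0.1581}
    direct_treatment: {mean: 71329.86, lo: 69890.76, hi: 72768.96}
    components:
      operative_treatment: 6543.83
      operative_materials: 43751.21
      medicine: 6984.55
      nursing: 844.83
  evt_ivt:
    label: "EVT + IVT"
    mrs_3m: {good: 0.5073, poor: 0.3443, dead: 0.1484}
    direct_treatment: {mean: 108463.60, lo: 86765.90, hi: 130161.30}
    components:
      operative_treatment: 10041.25
      operative_materials: 52879.26
      medicine: 13285.07
      nursing: 3035.45

transitions:
  good_to_good: 0.9550
  good_to_poor: 0.0240
  poor_to_good: 0.0290
  poor_to_poor: 0.9190
  recurrence_annual: 0.0960

costs:
  post_hosp_annual_good: {mean: 7385.00, lo: 7157.00, hi: 7619.00}
  post_hosp_annual_poor: {mean: 11350.00, lo: 10730.00, hi: 11996.00}
  indirect_total: 57595.37
  dalys: 7.95
  # value_per_daly omitted -> back-solved as indirect_total / dalys so the
  # product reproduces the published indirect-cost total exactly.

utilities:
  good: {mean: 0.76, lo: 0.69, hi: 0.82}
  poor: {mean: 0.21, lo: 0.17, hi: 0.26}
  dead: 0.00
  recurrent: {mean: 0.20, lo: 0.16, hi: 0.26}

economics:
  discount_annual: 0.03
  cycle_length_years: 0.25
  wtp_low: 90620
  wtp_high: 271860
  termination_mortality: 0.99
  max_cycles: 200
  base_year: 2023
  median_age_evt: 71
  median_age_evt_ivt: 70

psa:
  n_eff_dirichlet: 600
  recurrence_interval_frac: 0.20

model_options:
  indirect_mode: per_death      # one of: excluded | lump_sum | per_death
  transitions_are_annual: false
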