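# Full pipeline config: a small catchment grid with high CHW capture,
# validated against an error-free census, plus a toy cost ledger.
# Run:  chwvitals all --config examples/mali_like.yaml --seed 1 --out scratch/mali
simulation:
  n_catchments: 8
  households_per_catchment: 100
  women_per_household: 2
  monthly_birth_prob: 0.045
  srb_true: 105.0
  hazard_neonatal: 0.06
  hazard_postneonatal: 0.06
  hazard_child: 0.05
  stillbirth_prob: 0.02
  sim_start_cmc: 1351    # Jul 2012
  sim_end_cmc: 1365      # Sep 2013 (15-month horizon)

capture:
  p_capture_birth: 0.903
  p_capture_death_neonatal: 0.908
  p_capture_death_postneonatal: 0.908
  p_capture_death_child: 0.908
  p_monthly_report_missing: 0.0
  p_stillbirth_as_neonatal: 0.05

survey:
  design: census
  interview_cmc: 1366
  p_omit_per_year_recall: 0.05
  p_heap_to_12m: 0.3
  date_displacement_sd: 0.5

costing:
  items:
    - {category: central_salaries, amount: 120000, currency: XOF, year: 2012}
    - {category: supervision, amount: 60000, currency: XOF, year: 2013}
    - {category: training_equipment, amount: 45000, currency: XOF, year: 2012}
  cpi_series: {2012: 98.5, 2013: 99.4, 2014: 100.0}
  fx_rate: 494.0   # local units per USD at base year
  base_year: 2014

seed: 1
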