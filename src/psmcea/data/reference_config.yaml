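# Reference configuration: French cost-effectiveness model of first-line
# alectinib vs crizotinib in ALK+ NSCLC (2017 euros).
# Unit costs without a published value (ceritinib / pemetrexed+cisplatin
# acquisition, weekly disease-management costs, per-event AE costs) are
# package defaults chosen to the magnitude the published cost totals imply;
# see docs/methods.md.

settings:
  cycle_length_weeks: 1
  horizon_years: 10.0
  discount_rate_annual: 0.04
  weeks_per_year: 52
  half_cycle_correction: true
  entry_age_years: 55.0

intervention: alectinib
comparator: crizotinib

arms:
  alectinib:
    name: alectinib
    n_patients: 152
    pfs_median_months: 25.7
    os_rate_at_end: 0.77
    trial_end_months: 29.0
    censor_time_months: 29.0
    bm_baseline: 0.25
    bm_cumulative: 0.094
    duration_mean_months: 32.6
    duration_median_months: 18.6
    ae_incidences:
      acute_kidney_failure: 0.020
      ast_elevation: 0.039
      anaemia: 0.020
      alt_elevation: 0.053
      bilirubinaemia: 0.020
      diarrhoea: 0.0
      qt_prolongation: 0.0
      nausea: 0.0
      neutropenia: 0.0
      infection: 0.013
      vomiting: 0.0
  crizotinib:
    name: crizotinib
    n_patients: 151
    pfs_median_months: 10.4
    os_rate_at_end: 0.735
    trial_end_months: 27.0
    censor_time_months: 27.0
    bm_baseline: 0.25
    bm_cumulative: 0.414
    duration_mean_months: 16.7
    duration_median_months: 17.6
    ae_incidences:
      acute_kidney_failure: 0.0
      ast_elevation: 0.139
      anaemia: 0.0
      alt_elevation: 0.093
      bilirubinaemia: 0.0
      diarrhoea: 0.020
      qt_prolongation: 0.033
      nausea: 0.020
      neutropenia: 0.026
      infection: 0.020
      vomiting: 0.020

drugs:
  alectinib: {kind: oral, monthly_cost: 4993.63}
  crizotinib: {kind: oral, monthly_cost: 4473.07}
  ceritinib: {kind: oral, monthly_cost: 4900.00}
  pemetrexed_cisplatin: {kind: iv, session_cost: 1350.00, session_interval_days: 21.0}

costs:
  chemo_admin_per_session: 419.57
  monitoring_first_line: {alectinib: 23.76, crizotinib: 23.76}
  monitoring_second_line: 23.68
  monitoring_third_line: 24.40
  management_weekly_pfs: 25.00
  management_weekly_pps: 50.00
  bm_weekly: 114.30
  transport_round_trip: 79.95
  ae_event_costs:
    acute_kidney_failure: 8000.00
    ast_elevation: 4000.00
    anaemia: 3900.00
    alt_elevation: 4000.00
    bilirubinaemia: 4000.00
    diarrhoea: 3200.00
    qt_prolongation: 4400.00
    nausea: 2900.00
    neutropenia: 5200.00
    infection: 7900.00
    vomiting: 2900.00
  ae_cost_multiplier: {alectinib: 1.0, crizotinib: 1.0}
  ae_reweighting: {alectinib: 1.0, crizotinib: 1.0}
  second_line_duration_weeks: 50.1
  first_line_drug: {alectinib: alectinib, crizotinib: crizotinib}
  second_line_mix:
    alectinib: {ceritinib: 1.0}
    crizotinib: {alectinib: 0.8, ceritinib: 0.2}
  third_line_mix:
    alectinib: {pemetrexed_cisplatin: 1.0}
    crizotinib: {pemetrexed_cisplatin: 1.0}

utilities:
  pfs: 0.831
  pps_second_line: 0.743
  pps_third_line: 0.586
  default_ae_disutility: -0.061
  ae_disutility_duration_weeks: 4.0
  ae_disutilities:
    acute_kidney_failure: -0.061
    alt_elevation: -0.061
    anaemia: -0.073
    ast_elevation: -0.061
    diarrhoea: -0.047
    bilirubinaemia: -0.061
    infection: -0.061
    nausea: -0.047
    neutropenia: -0.090
    qt_prolongation: -0.061
    vomiting: -0.048

events:
  bm_baseline: 0.25

extrapolation:
  cutover_weeks: 78
  pfs_family: exponential
  duration_family: exponential
  os_family: gamma
  os_reference_arm: crizotinib
  bm_tail_family: exponential

dsa:
  - {name: Age, path: settings.entry_age_years, base: 55.0, low: 44.04, high: 66.06}
  - {name: Utility in PFS, path: utilities.pfs, base: 0.831, low: 0.828, high: 0.835}
  - {name: Utility progression 2nd line, path: utilities.pps_second_line, base: 0.743, low: 0.726, high: 0.760}
  - {name: Utility progression 3rd line, path: utilities.pps_third_line, base: 0.586, low: 0.469, high: 0.631}
  - {name: Patients with BM at entry, path: events.bm_baseline, base: 0.25, low: 0.15, high: 0.35}
  - {name: Discount rate, path: settings.discount_rate_annual, base: 0.04, low: 0.015, high: 0.06}
  - {name: Administration cost chemotherapy, path: costs.chemo_admin_per_session, base: 419.57, low: 335.66, high: 503.48}
  - {name: Monitoring cost for alectinib, path: costs.monitoring_first_line.alectinib, base: 23.76, low: 19.06, high: 28.46}
  - {name: Monitoring cost for crizotinib, path: costs.monitoring_first_line.crizotinib, base: 23.76, low: 19.06, high: 28.46}
  - {name: Monitoring cost 2nd line PP, path: costs.monitoring_second_line, base: 23.68, low: 18.94, high: 28.42}
  - {name: Monitoring cost 3rd line PP, path: costs.monitoring_third_line, base: 24.40, low: 19.52, high: 29.28}
  - {name: Treatment duration 2nd line, path: costs.second_line_duration_weeks, base: 50.1, low: 40.1, high: 60.1}
  - {name: Management cost for AE alectinib, path: costs.ae_cost_multiplier.alectinib, base: 1.0, low: 0.8, high: 1.2}
  - {name: Management cost for AE crizotinib, path: costs.ae_cost_multiplier.crizotinib, base: 1.0, low: 0.8, high: 1.2}
  - {name: Management cost for BM/week, path: costs.bm_weekly, base: 114.30, low: 91.44, high: 137.16}

# PSA distribution means are the base-case values; standard deviations for
# utilities come from the published 95% CIs ((high - low) / 3.92) and for
# costs from the +/-20% one-way ranges treated the same way.
psa:
  iterations: 1000
  include_survival: true
  wtp_grid_max: 300000.0
  wtp_grid_step: 5000.0
  parameters:
    - {name: Utility in PFS, path: utilities.pfs, distribution: gamma, mean: 0.831, sd: 0.001786}
    - {name: Utility progression 2nd line, path: utilities.pps_second_line, distribution: gamma, mean: 0.743, sd: 0.008673}
    - {name: Utility progression 3rd line, path: utilities.pps_third_line, distribution: gamma, mean: 0.586, sd: 0.041327}
    - {name: Administration cost chemotherapy, path: costs.chemo_admin_per_session, distribution: log-normal, mean: 419.57, sd: 42.811}
    - {name: Monitoring cost for alectinib, path: costs.monitoring_first_line.alectinib, distribution: log-normal, mean: 23.76, sd: 2.398}
    - {name: Monitoring cost for crizotinib, path: costs.monitoring_first_line.crizotinib, distribution: log-normal, mean: 23.76, sd: 2.398}
    - {name: Monitoring cost 2nd line PP, path: costs.monitoring_second_line, distribution: log-normal, mean: 23.68, sd: 2.418}
    - {name: Monitoring cost 3rd line PP, path: costs.monitoring_third_line, distribution: log-normal, mean: 24.40, sd: 2.490}
    - {name: Management cost for BM/week, path: costs.bm_weekly, distribution: log-normal, mean: 114.30, sd: 11.663}

scenario:
  name: real-world pathway
  second_line_mix:
    alectinib: {ceritinib: 0.5, pemetrexed_cisplatin: 0.5}
    crizotinib: {alectinib: 0.8, ceritinib: 0.2}

seeds:
  trial: 12345
  psa: 67890
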