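# Intent-to-treat population (n = 628): all randomized patients.
population: ITT
survival:
  pembrolizumab:
    os: {family: lognormal, params: {meanlog: 1.95, sdlog: 1.04}}
    pfs: {family: loglogistic, params: {shape: 1.882, scale: 2.742}}
  chemotherapy:
    os: {family: gamma, params: {shape: 1.4504, rate: 0.1728}}
    pfs: {family: lognormal, params: {meanlog: 1.27, sdlog: 0.9}}
costs:
  pembrolizumab: 10323.2
  paclitaxel: 79.5
  docetaxel: 87.0
  irinotecan: 61.0
  administration: 69.81
  laboratory: 87.6
  follow_up: 51.5
  best_supportive_care: 117.1
utilities:
  pfs: 0.741
  pd: 0.581
  death: 0.0
adverse_events:
  costs:
    fatigue: 110.3
    decreased_appetite: 115.4
    asthenia: 115.4
    diarrhea: 44.6
    anemia: 508.2
    neutrophil_count_decreased: 466.0
    wbc_count_decreased: 466.0
    neutropenia: 466.0
  risks:
    pembrolizumab:
      fatigue: 0.006
      decreased_appetite: 0.006
      asthenia: 0.013
      diarrhea: 0.006
      anemia: 0.013
    chemotherapy:
      diarrhea: 0.03
      anemia: 0.078
      neutrophil_count_decreased: 0.098
      wbc_count_decreased: 0.101
      neutropenia: 0.071
settings:
  cycle_length_days: 21.0
  horizon_years: 10.0
  annual_discount: 0.03
  wtp: 150000.0
  half_cycle_correction: false
  days_per_month: 30.4375
sensitivity:
  range_fraction: 0.2
  n_iterations: 10000
  seed: 2022
  psa_interval_z: 1.96
  wtp_grid:
    start: 0.0
    stop: 300000.0
    step: 5000.0
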