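# Model inputs for therapeutic radiographer independent prescribers (TR-IP)
# vs TR non-prescribers (TR-NP), NHS England perspective, 2021 GBP.
# Schema as in dietitian.yaml.
profession: therapeutic_radiographer
currency_year: 2021

training:
  course_fee: {point: 1951, low: 1070, high: 4000, dist: gamma}
  annual_salary: {point: 48456, low: 44606, high: 52305, dist: fixed}
  employer_paid_days: {point: 7, low: 2, high: 14, dist: gamma}
  taught_days: 26
  supervised_days: 12
  work_time_fraction: 0.5
  personal_study_days: {point: 27, low: 4, high: 60, dist: gamma}
  oop_travel: {point: 209, low: 36, high: 600, dist: gamma}
  oop_materials: {point: 62, low: 20, high: 150, dist: gamma}
  oop_other: {point: 45, low: 25, high: 60, dist: gamma}

activity:
  prescriber:
    contacts_per_week: {point: 19, low: 6, high: 38, dist: gamma}
    # 12 of 19 weekly contacts need prescription management (range 4-24)
    p_require_rx: {point: 0.6316, low: 0.2105, high: 1.0, dist: beta}
    p_use_rights: {point: 0.87, low: 0.435, high: 1.0, dist: beta}
    p_refer: {point: 0.07, low: 0.035, high: 0.105, dist: beta}
    c_consult_std: {point: 87, low: 52, high: 127, dist: gamma}
    c_consult_rx: {point: 116, low: 69, high: 168, dist: gamma}
    c_referral: {point: 179, low: 76, high: 364, dist: gamma}
    time_shares:
      communicating: {point: 0.43, low: 0.25, high: 0.70}
      reviewing_medication: {point: 0.33, low: 0.05, high: 0.85}
      consulting_colleagues: {point: 0.13, low: 0.10, high: 0.20}
      writing_notes: {point: 0.28, low: 0.15, high: 0.45}
  non_prescriber:
    contacts_per_week: {point: 19, low: 6, high: 38, dist: gamma}
    p_require_rx: {point: 0.6316, low: 0.2105, high: 1.0, dist: beta}
    p_use_rights: 0.0
    p_refer: {point: 0.23, low: 0.115, high: 0.345, dist: beta}
    c_consult_std: {point: 87, low: 52, high: 127, dist: gamma}
    c_consult_rx: {point: 87, low: 52, high: 127, dist: gamma}
    c_referral: {point: 179, low: 76, high: 364, dist: gamma}

effects:
  qaly:
    prescriber: {mean: 0.7299, sd: 0.0250}
    non_prescriber: {mean: 0.7359, sd: 0.0291}
    difference: -0.0060
    ci95: [-0.0816, 0.0686]
  satisfaction:
    prescriber: {mean: 79.57, sd: 0.96}
    non_prescriber: {mean: 79.35, sd: 0.66}
    difference: 0.22
    ci95: [-0.0556, 0.5002]
  experience:
    prescriber: {mean: 65.69, sd: 0.97}
    non_prescriber: {mean: 66.24, sd: 1.09}
    difference: -0.55
    ci95: [-0.9140, -0.1867]

reported:
  training_components:
    employer_study_cost: 951
    time_off_cost: 2522
    personal_study_cost: 3584
  training_totals:
    include_oop: {point: 9324, low: 4470, high: 17223}
    exclude_oop: {point: 5425, low: 3858, high: 8447}
  per_patient_cost:
    prescriber: {mean: 134, sd: 61}
    non_prescriber: {mean: 129, sd: 71}
  arm_totals:
    year1: {prescriber: 121918, non_prescriber: 117422}
    year5: {prescriber: 613102, non_prescriber: 629672}
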