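# Model inputs for dietitian supplementary prescribers (D-SP) vs dietitian
# non-prescribers (D-NP), NHS England perspective, 2021 GBP.
# Each ranged parameter is {point, low, high, dist}; a bare scalar means a
# fixed (zero-width) parameter. `reported` holds published summary numbers
# that are survey-sample means and therefore not exactly recomputable from
# the rounded per-day inputs above them.
profession: dietitian
currency_year: 2021

training:
  course_fee: {point: 1801, low: 1200, high: 3500, dist: gamma}
  annual_salary: {point: 48456, low: 44606, high: 52305, dist: fixed}
  employer_paid_days: {point: 6, low: 1, high: 11, dist: gamma}
  taught_days: 26
  supervised_days: 12
  work_time_fraction: 0.5
  personal_study_days: {point: 29, low: 7, high: 60, dist: gamma}
  oop_travel: {point: 132, low: 10, high: 400, dist: gamma}
  oop_materials: {point: 105, low: 10, high: 400, dist: gamma}
  oop_other: {point: 193, low: 30, high: 400, dist: gamma}

activity:
  prescriber:
    contacts_per_week: {point: 9, low: 5, high: 15, dist: gamma}
    # 6 of 9 weekly contacts need prescription management (range 3-9 of 5-15)
    p_require_rx: {point: 0.6667, low: 0.3333, high: 1.0, dist: beta}
    # prescribing qualification used in 64% of consultations; bounds are the
    # package's +/-50% convention (published appendix bounds unavailable)
    p_use_rights: {point: 0.64, low: 0.32, high: 0.96, dist: beta}
    p_refer: {point: 0.02, low: 0.01, high: 0.03, dist: beta}
    c_consult_std: {point: 123, low: 98, high: 149, dist: gamma}
    c_consult_rx: {point: 157, low: 125, high: 190, dist: gamma}
    c_referral: {point: 188, low: 76, high: 364, dist: gamma}
    time_shares:
      communicating: {point: 0.23, low: 0.20, high: 0.25}
      reviewing_medication: {point: 0.28, low: 0.25, high: 0.30}
      consulting_colleagues: {point: 0.55, low: 0.10, high: 1.00}
      writing_notes: 0.10
  non_prescriber:
    contacts_per_week: {point: 9, low: 5, high: 15, dist: gamma}
    p_require_rx: {point: 0.6667, low: 0.3333, high: 1.0, dist: beta}
    p_use_rights: 0.0
    p_refer: {point: 0.30, low: 0.15, high: 0.45, dist: beta}
    c_consult_std: {point: 123, low: 98, high: 149, dist: gamma}
    c_consult_rx: {point: 123, low: 98, high: 149, dist: gamma}
    c_referral: {point: 188, low: 76, high: 364, dist: gamma}

effects:
  qaly:
    prescriber: {mean: 0.7403, sd: 0.0223}
    non_prescriber: {mean: 0.7525, sd: 0.0269}
    difference: -0.0122
    ci95: [-0.0817, 0.0551]
  satisfaction:
    prescriber: {mean: 77.32, sd: 7.38}
    non_prescriber: {mean: 76.38, sd: 7.63}
    difference: 0.95
    ci95: [-3.37, 5.26]
  experience:
    prescriber: {mean: 65.20, sd: 7.39}
    non_prescriber: {mean: 63.33, sd: 5.65}
    difference: 1.87
    ci95: [-1.93, 5.66]

reported:
  # published component means (computed on unrounded survey data)
  training_components:
    employer_study_cost: 797
    time_off_cost: 2522
    personal_study_cost: 3791
  training_totals:
    include_oop: {point: 9341, low: 4834, high: 16654}
    exclude_oop: {point: 5120, low: 3855, high: 7489}
  # per-patient annual cost, mean (sd), by arm
  per_patient_cost:
    prescriber: {mean: 169, sd: 34}
    non_prescriber: {mean: 179, sd: 69}
  # per-prescriber arm totals, 1-year and discounted 5-year horizons
  arm_totals:
    year1: {prescriber: 74820, non_prescriber: 79206}
    year5: {prescriber: 360469, non_prescriber: 424738}
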