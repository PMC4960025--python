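# Base-case model configuration (2013 GBP).

discount:
  annual_rate: 0.035
  reference_age: 30        # presentation age; discounting origin

staffing:
  london_weighting_factor: 1.19
  supervision_hours_per_counsellor_hour: 0.08   # 1 h consultant per 12.5 h counsellor

appointments:
  duration_minutes: 45
  consultant_rate_label: consultant
  counsellor_rate_label: band8_genetic_counsellor
  # No published price for a telephone appointment; default calibrated to the
  # telephone-mix sensitivity rows given the modelled appointment count.
  telephone_unit_cost_gbp: "62.17"

# Age-indexed imaging streams per risk tier. Events fall on an arithmetic
# grid per segment, start inclusive / end exclusive; all are discountable.
surveillance:
  population:
    - {modality: mammography, start_age: 50, end_age: 70, interval_years: 3}
  moderate:
    - {modality: mammography, start_age: 40, end_age: 50, interval_years: 1}
    - {modality: mammography, start_age: 50, end_age: 70, interval_years: 3}
  higher:
    - {modality: mammography, start_age: 40, end_age: 50, interval_years: 1}
    - {modality: mammography, start_age: 50, end_age: 60, interval_years: 1.5}
    - {modality: mammography, start_age: 60, end_age: 70, interval_years: 3}
  carrier:
    - {modality: mammography, start_age: 40, end_age: 70, interval_years: 1}
    - {modality: mri, start_age: 30, end_age: 50, interval_years: 1}

interventions:
  mastectomy_uptake_unaffected: 0.30
  bso_uptake_unaffected: 0.60
  five_year_survival:
    breast: 0.70
    ovarian: 0.69
  post_ovarian_mastectomy_rate: 0.05   # of 5-year survivors with a mutation

# Metadata for components estimated by calibration (no printed unit price).
# staff_fraction: share of the component that is staff-time derived and hence
# subject to the London weighting toggle.
calibrated_components:
  gp_referral: {category: referral, staff_fraction: 0.0}
  predictive_test: {category: test, staff_fraction: 0.0}
  surveillance_population: {category: management, staff_fraction: 0.0}
  surveillance_moderate: {category: management, staff_fraction: 0.0}
  surveillance_higher: {category: management, staff_fraction: 0.0}
  management_affected_carrier: {category: management, staff_fraction: 0.0}
  management_unaffected_carrier: {category: management, staff_fraction: 0.0}
  relative_coordination_full_positive: {category: administration, staff_fraction: 1.0}
  relative_coordination_full_negative: {category: administration, staff_fraction: 1.0}
  relative_coordination_predictive: {category: administration, staff_fraction: 1.0}
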