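[
  {
    "condition": "GBS_FISHER",
    "n_cases": 200,
    "criterion_prevalence": {
      "bilateral_weakness": 1.0,
      "flaccid_weakness": 0.95,
      "dtr_decreased_in_weak_limbs": 0.91,
      "onset_nadir_12h_28d": 1.0,
      "alt_dx_absent": 1.0,
      "electrophys_consistent": 0.88,
      "csf_wbc_lt50": 0.95,
      "csf_protein_elevated": 0.8
    },
    "criterion_missingness": {
      "electrophys_consistent": 0.27,
      "csf_wbc_lt50": 0.91,
      "csf_protein_elevated": 0.91
    },
    "prop_not_a_case": 0.09,
    "exclusion_criterion": "alt_dx_absent",
    "age_median": 26,
    "age_min": 15,
    "age_max": 58,
    "prop_male": 0.36,
    "prop_addis": 0.55,
    "prop_eopd": 0.64
  },
  {
    "condition": "THROMBOSIS_THROMBOEMBOLISM",
    "n_cases": 500,
    "criterion_prevalence": {
      "clinical_diagnosis_documented": 0.98,
      "imaging_confirmed": 0.85,
      "symptoms_at_site": 0.7
    },
    "criterion_missingness": {
      "imaging_confirmed": 0.15,
      "symptoms_at_site": 0.25
    },
    "prop_not_a_case": 0.02,
    "exclusion_criterion": "clinical_diagnosis_documented",
    "age_median": 49,
    "age_min": 16,
    "age_max": 88,
    "prop_male": 0.32,
    "prop_addis": 0.46,
    "prop_eopd": 0.93
  }
]
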