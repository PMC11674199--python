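{
  "condition": "GBS_FISHER",
  "version": "1.0",
  "criteria": [
    {"id": "bilateral_weakness", "label": "Bilateral weakness of limbs", "category": "CLINICAL"},
    {"id": "flaccid_weakness", "label": "Flaccid weakness of limbs", "category": "CLINICAL"},
    {"id": "dtr_decreased_in_weak_limbs", "label": "Decreased or absent deep tendon reflexes in weak limbs", "category": "CLINICAL"},
    {"id": "onset_nadir_12h_28d", "label": "Time between onset and nadir 12 h to 28 days", "category": "TEMPORAL"},
    {"id": "alt_dx_absent", "label": "Absence of identified alternative diagnosis for weakness", "category": "EXCLUSION"},
    {"id": "electrophys_consistent", "label": "Electrophysiologic findings consistent (AIDP, AMAN and/or AMSAN)", "category": "ELECTROPHYSIOLOGY"},
    {"id": "csf_wbc_lt50", "label": "CSF total white cell count < 50 cells/uL", "category": "LABORATORY"},
    {"id": "csf_protein_elevated", "label": "CSF protein elevated above laboratory normal", "category": "LABORATORY"}
  ],
  "levels": {
    "1": ["ALL", "bilateral_weakness", "flaccid_weakness", "dtr_decreased_in_weak_limbs", "onset_nadir_12h_28d", "alt_dx_absent", "csf_wbc_lt50", "csf_protein_elevated", "electrophys_consistent"],
    "2": ["ALL", "bilateral_weakness", "flaccid_weakness", "dtr_decreased_in_weak_limbs", "onset_nadir_12h_28d", "alt_dx_absent", ["ANY", "csf_wbc_lt50", "electrophys_consistent"]],
    "3": ["ALL", "bilateral_weakness", "flaccid_weakness", "dtr_decreased_in_weak_limbs", "onset_nadir_12h_28d", "alt_dx_absent"]
  }
}
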