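{
  "condition": "BELLS_PALSY",
  "version": "0.1-schema-example",
  "criteria": [
    {"id": "unilateral_facial_weakness", "label": "Unilateral facial weakness of peripheral nerve pattern", "category": "CLINICAL"},
    {"id": "rapid_onset_72h", "label": "Onset reaching maximum severity within 72 hours", "category": "TEMPORAL"},
    {"id": "facial_nerve_exam_documented", "label": "Complete facial nerve examination documented", "category": "CLINICAL"},
    {"id": "alt_dx_absent", "label": "No identified alternative cause of facial weakness", "category": "EXCLUSION"}
  ],
  "levels": {
    "1": ["ALL", "unilateral_facial_weakness", "alt_dx_absent", "rapid_onset_72h", "facial_nerve_exam_documented"],
    "2": ["ALL", "unilateral_facial_weakness", "alt_dx_absent", "rapid_onset_72h"],
    "3": ["ALL", "unilateral_facial_weakness", "alt_dx_absent"]
  }
}
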