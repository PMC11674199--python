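{
  "condition": "THROMBOSIS_THROMBOEMBOLISM",
  "version": "1.0-simplified",
  "criteria": [
    {"id": "clinical_diagnosis_documented", "label": "Documented clinical diagnosis of thrombosis or thromboembolism", "category": "CLINICAL"},
    {"id": "imaging_confirmed", "label": "Site-specific imaging confirmation of thrombosis", "category": "IMAGING"},
    {"id": "symptoms_at_site", "label": "Symptoms or signs referable to the thrombosed site", "category": "CLINICAL"}
  ],
  "levels": {
    "1": ["ALL", "clinical_diagnosis_documented", "imaging_confirmed", "symptoms_at_site"],
    "2": ["ALL", "clinical_diagnosis_documented", "imaging_confirmed"],
    "3": "clinical_diagnosis_documented"
  }
}
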