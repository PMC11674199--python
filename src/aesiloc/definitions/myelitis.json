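{
  "condition": "MYELITIS",
  "version": "1.0-simplified",
  "criteria": [
    {"id": "focal_cns_sign", "label": "Myelopathy: motor, sensory, or autonomic spinal cord sign", "category": "CLINICAL"},
    {"id": "fever", "label": "Fever", "category": "CLINICAL"},
    {"id": "csf_pleocytosis", "label": "CSF pleocytosis", "category": "LABORATORY"},
    {"id": "eeg_consistent", "label": "EEG findings consistent with CNS inflammation", "category": "ELECTROPHYSIOLOGY"},
    {"id": "neuroimaging_consistent", "label": "Spinal cord neuroimaging consistent with inflammation", "category": "IMAGING"},
    {"id": "histopathology", "label": "Histopathologic demonstration of spinal cord inflammation", "category": "LABORATORY"}
  ],
  "levels": {
    "1": ["ALL", "focal_cns_sign", ["AT_LEAST", 2, "fever", "csf_pleocytosis", "eeg_consistent", "neuroimaging_consistent"], ["ANY", "histopathology", ["ALL", "neuroimaging_consistent", "csf_pleocytosis"]]],
    "2": ["ALL", "focal_cns_sign", ["AT_LEAST", 2, "fever", "csf_pleocytosis", "eeg_consistent", "neuroimaging_consistent"]],
    "3": ["ALL", "focal_cns_sign", ["AT_LEAST", 1, "fever", "csf_pleocytosis", "eeg_consistent", "neuroimaging_consistent"]]
  }
}
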