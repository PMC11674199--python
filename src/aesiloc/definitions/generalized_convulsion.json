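{
  "condition": "GENERALIZED_CONVULSION",
  "version": "1.0-simplified",
  "criteria": [
    {"id": "generalized_motor_seizure", "label": "Witnessed sudden generalized motor manifestation", "category": "CLINICAL"},
    {"id": "bilateral_motor", "label": "Motor involvement of both right and left limbs", "category": "CLINICAL"},
    {"id": "loss_of_consciousness", "label": "Loss or impairment of consciousness during the event", "category": "CLINICAL"},
    {"id": "witnessed_by_clinician", "label": "Event witnessed or documented by a health professional", "category": "CLINICAL"},
    {"id": "eeg_epileptiform", "label": "Epileptiform activity on EEG", "category": "ELECTROPHYSIOLOGY"}
  ],
  "levels": {
    "1": ["ALL", "generalized_motor_seizure", "bilateral_motor", "loss_of_consciousness", "witnessed_by_clinician", "eeg_epileptiform"],
    "2": ["ALL", "generalized_motor_seizure", "bilateral_motor", "loss_of_consciousness", "witnessed_by_clinician"],
    "3": ["ALL", "generalized_motor_seizure", "bilateral_motor", "loss_of_consciousness"]
  }
}
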