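{
  "condition": "MYOCARDITIS",
  "version": "1.0-simplified",
  "criteria": [
    {"id": "compatible_symptoms", "label": "Clinical symptoms compatible with myocarditis", "category": "CLINICAL"},
    {"id": "ecg_abnormal", "label": "ECG abnormality consistent with myocarditis", "category": "ELECTROPHYSIOLOGY"},
    {"id": "biomarker_elevated", "label": "Elevated myocardial biomarkers (troponin / CK-MB)", "category": "LABORATORY"},
    {"id": "cmr_abnormal", "label": "Cardiac MRI findings consistent with myocarditis", "category": "IMAGING"},
    {"id": "echo_abnormal", "label": "Echocardiographic abnormality consistent with myocarditis", "category": "IMAGING"},
    {"id": "histopathology", "label": "Histopathologic demonstration of myocardial inflammation", "category": "LABORATORY"}
  ],
  "levels": {
    "1": ["ALL", "compatible_symptoms", "biomarker_elevated", ["ANY", "histopathology", "cmr_abnormal", "echo_abnormal"]],
    "2": ["ALL", "compatible_symptoms", "biomarker_elevated"],
    "3": ["ALL", "compatible_symptoms", ["ANY", "ecg_abnormal", "biomarker_elevated"]]
  }
}
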