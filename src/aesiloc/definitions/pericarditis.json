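{
  "condition": "PERICARDITIS",
  "version": "1.0-simplified",
  "criteria": [
    {"id": "typical_chest_pain", "label": "Typical pericarditic chest pain", "category": "CLINICAL"},
    {"id": "pericardial_rub", "label": "Pericardial friction rub on auscultation", "category": "CLINICAL"},
    {"id": "ecg_typical", "label": "ECG findings typical of pericarditis", "category": "ELECTROPHYSIOLOGY"},
    {"id": "effusion_imaging", "label": "Pericardial effusion on imaging", "category": "IMAGING"},
    {"id": "chest_radiograph_suggestive", "label": "Chest radiograph suggestive of pericardial disease", "category": "IMAGING"},
    {"id": "histopathology", "label": "Histopathologic demonstration of pericardial inflammation", "category": "LABORATORY"}
  ],
  "levels": {
    "1": ["ALL", ["ANY", "typical_chest_pain", "pericardial_rub"], ["ANY", "ecg_typical", "effusion_imaging"], ["ANY", "histopathology", ["ALL", "ecg_typical", "effusion_imaging"]]],
    "2": ["ALL", ["ANY", "typical_chest_pain", "pericardial_rub"], ["ANY", "ecg_typical", "effusion_imaging"]],
    "3": ["ALL", ["ANY", "typical_chest_pain", "pericardial_rub"], ["ANY", "ecg_typical", "chest_radiograph_suggestive", "effusion_imaging"]]
  }
}
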