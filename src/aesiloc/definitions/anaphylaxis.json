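{
  "condition": "ANAPHYLAXIS",
  "version": "0.1-schema-example",
  "criteria": [
    {"id": "sudden_onset", "label": "Sudden onset and rapid progression of signs and symptoms", "category": "TEMPORAL"},
    {"id": "skin_mucosal", "label": "Skin or mucosal involvement", "category": "CLINICAL"},
    {"id": "respiratory_compromise", "label": "Respiratory compromise", "category": "CLINICAL"},
    {"id": "cardiovascular_compromise", "label": "Cardiovascular compromise", "category": "CLINICAL"}
  ],
  "levels": {
    "1": ["ALL", "sudden_onset", "skin_mucosal", ["AT_LEAST", 1, "respiratory_compromise", "cardiovascular_compromise"]],
    "2": ["ALL", "sudden_onset", ["AT_LEAST", 2, "skin_mucosal", "respiratory_compromise", "cardiovascular_compromise"]],
    "3": ["ALL", "sudden_onset", ["AT_LEAST", 1, "skin_mucosal", "respiratory_compromise", "cardiovascular_compromise"]]
  }
}
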