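{
  "condition": "TTS",
  "version": "0.1-schema-example",
  "criteria": [
    {"id": "platelet_lt150", "label": "Platelet count < 150 x 10^9/L", "category": "LABORATORY"},
    {"id": "thrombosis_imaging_confirmed", "label": "Thrombosis confirmed by site-specific imaging", "category": "IMAGING"},
    {"id": "thrombosis_clinical", "label": "Documented clinical diagnosis of thrombosis", "category": "CLINICAL"}
  ],
  "levels": {
    "1": ["ALL", "platelet_lt150", "thrombosis_imaging_confirmed"],
    "2": ["ALL", "platelet_lt150", ["ANY", "thrombosis_imaging_confirmed", "thrombosis_clinical"]],
    "3": ["ALL", "platelet_lt150", ["ANY", "thrombosis_imaging_confirmed", "thrombosis_clinical"]]
  }
}
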