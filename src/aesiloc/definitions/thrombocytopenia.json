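{
  "condition": "THROMBOCYTOPENIA",
  "version": "1.0-simplified",
  "criteria": [
    {"id": "platelet_lt150", "label": "Platelet count < 150 x 10^9/L", "category": "LABORATORY"},
    {"id": "platelet_lt150_repeat", "label": "Thrombocytopenia confirmed on repeat count", "category": "LABORATORY"},
    {"id": "bleeding_symptoms", "label": "Clinical bleeding manifestations", "category": "CLINICAL"}
  ],
  "levels": {
    "1": ["ALL", "platelet_lt150", "platelet_lt150_repeat"],
    "2": ["ALL", "platelet_lt150", ["ANY", "platelet_lt150_repeat", "bleeding_symptoms"]],
    "3": "platelet_lt150"
  }
}
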