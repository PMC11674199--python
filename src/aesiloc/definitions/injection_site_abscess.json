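{
  "condition": "INJECTION_SITE_ABSCESS",
  "version": "0.1-schema-example",
  "criteria": [
    {"id": "injection_site_mass", "label": "Localized mass or fluctuance at the injection site", "category": "CLINICAL"},
    {"id": "inflammation_signs", "label": "Localized pain, warmth, or erythema", "category": "CLINICAL"},
    {"id": "purulent_drainage", "label": "Purulent material drained or aspirated", "category": "LABORATORY"}
  ],
  "levels": {
    "1": ["ALL", "injection_site_mass", "purulent_drainage"],
    "2": ["ALL", "injection_site_mass", ["ANY", "purulent_drainage", "inflammation_signs"]],
    "3": "injection_site_mass"
  }
}
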