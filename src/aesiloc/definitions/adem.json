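{
  "condition": "ADEM",
  "version": "0.1-schema-example",
  "criteria": [
    {"id": "multifocal_cns_deficits", "label": "Multifocal central nervous system deficits", "category": "CLINICAL"},
    {"id": "encephalopathy", "label": "Encephalopathy", "category": "CLINICAL"},
    {"id": "mri_demyelination", "label": "MRI findings of diffuse or multifocal demyelination", "category": "IMAGING"},
    {"id": "alt_dx_absent", "label": "No identified alternative diagnosis (monophasic illness)", "category": "EXCLUSION"}
  ],
  "levels": {
    "1": ["ALL", "multifocal_cns_deficits", "alt_dx_absent", "encephalopathy", "mri_demyelination"],
    "2": ["ALL", "multifocal_cns_deficits", "alt_dx_absent", ["ANY", "encephalopathy", "mri_demyelination"]],
    "3": ["ALL", "multifocal_cns_deficits", "alt_dx_absent"]
  }
}
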