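{
  "categories": {
    "CRS": ["Cytokine release syndrome"],
    "ICANS": ["Immune effector cell-associated neurotoxicity syndrome"],
    "non-ICANS neurotoxicity": [
      "Bell's palsy",
      "Facial paralysis",
      "Parkinsonism",
      "Encephalopathy",
      "Tremor",
      "Aphasia",
      "Delirium",
      "Cranial nerve disorder",
      "Peripheral neuropathy",
      "Progressive multifocal leukoencephalopathy"
    ],
    "pneumonia": ["Pneumonia"],
    "sepsis": ["Sepsis", "Septic shock"],
    "COVID-19 infection": ["COVID-19", "COVID-19 pneumonia"],
    "infection": ["Infection"],
    "Pneumocystis jirovecii pneumonia": ["Pneumocystis jirovecii pneumonia"],
    "CMV reactivation": ["Cytomegalovirus infection reactivation", "Cytomegalovirus infection"],
    "CMV pneumonia": ["Cytomegalovirus pneumonia"]
  },
  "composites": {
    "infection (composite)": [
      "pneumonia",
      "sepsis",
      "COVID-19 infection",
      "infection",
      "Pneumocystis jirovecii pneumonia",
      "CMV reactivation",
      "CMV pneumonia"
    ]
  },
  "progression_terms": [
    "Disease progression",
    "Malignant neoplasm progression",
    "Multiple myeloma"
  ]
}
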