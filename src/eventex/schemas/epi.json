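{
  "name": "EPI",
  "entity_types": {"Protein": null, "Entity": null},
  "given_types": ["Protein"],
  "site_mode": "trigger-linked",
  "resolve_equiv": true,
  "modality_types": ["Negation", "Speculation"],
  "reverse_event_types": {
    "Phosphorylation": "Dephosphorylation",
    "Hydroxylation": "Dehydroxylation",
    "Ubiquitination": "Deubiquitination",
    "DNA_methylation": "DNA_demethylation",
    "Glycosylation": "Deglycosylation",
    "Acetylation": "Deacetylation",
    "Methylation": "Demethylation"
  },
  "event_types": {
    "Phosphorylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Dephosphorylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Hydroxylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Dehydroxylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Ubiquitination": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Deubiquitination": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "DNA_methylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "DNA_demethylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Glycosylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Deglycosylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Acetylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Deacetylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Methylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Demethylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Catalysis": {
      "Theme": {"targets": ["Event"]},
      "Cause": {"targets": ["Protein"]}
    }
  }
}
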