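{
  "name": "GE",
  "entity_types": {"Protein": null, "Entity": null},
  "given_types": ["Protein"],
  "site_mode": "protein-linked",
  "resolve_equiv": true,
  "modality_types": ["Negation", "Speculation"],
  "event_types": {
    "Gene_expression": {
      "Theme": {"targets": ["Protein"]}
    },
    "Transcription": {
      "Theme": {"targets": ["Protein"]}
    },
    "Protein_catabolism": {
      "Theme": {"targets": ["Protein"]}
    },
    "Phosphorylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Localization": {
      "Theme": {"targets": ["Protein"]},
      "AtLoc": {"targets": ["Entity"], "min": 0, "site": true},
      "ToLoc": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Binding": {
      "Theme": {"targets": ["Protein"], "max": null},
      "Site": {"targets": ["Entity"], "min": 0, "max": null, "site": true}
    },
    "Regulation": {
      "Theme": {"targets": ["Protein", "Event"]},
      "Cause": {"targets": ["Protein", "Event"], "min": 0},
      "Site": {"targets": ["Entity"], "min": 0, "site": true},
      "CSite": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Positive_regulation": {
      "Theme": {"targets": ["Protein", "Event"]},
      "Cause": {"targets": ["Protein", "Event"], "min": 0},
      "Site": {"targets": ["Entity"], "min": 0, "site": true},
      "CSite": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Negative_regulation": {
      "Theme": {"targets": ["Protein", "Event"]},
      "Cause": {"targets": ["Protein", "Event"], "min": 0},
      "Site": {"targets": ["Entity"], "min": 0, "site": true},
      "CSite": {"targets": ["Entity"], "min": 0, "site": true}
    }
  }
}
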