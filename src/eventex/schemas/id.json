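{
  "name": "ID",
  "entity_types": {
    "Protein": "Core_entity",
    "Two-component-system": "Core_entity",
    "Chemical": "Core_entity",
    "Organism": "Core_entity",
    "Regulon-operon": null,
    "Entity": null
  },
  "given_types": ["Protein", "Two-component-system", "Chemical", "Organism", "Regulon-operon"],
  "site_mode": "protein-linked",
  "resolve_equiv": true,
  "zero_argument_types": ["Process"],
  "modality_types": ["Negation", "Speculation"],
  "event_types": {
    "Gene_expression": {
      "Theme": {"targets": ["Protein", "Regulon-operon"]}
    },
    "Transcription": {
      "Theme": {"targets": ["Protein", "Regulon-operon"]}
    },
    "Protein_catabolism": {
      "Theme": {"targets": ["Protein"]}
    },
    "Phosphorylation": {
      "Theme": {"targets": ["Protein"]},
      "Site": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Localization": {
      "Theme": {"targets": ["Protein", "Core_entity"]},
      "AtLoc": {"targets": ["Entity"], "min": 0, "site": true},
      "ToLoc": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Binding": {
      "Theme": {"targets": ["Protein", "Core_entity"], "max": null},
      "Site": {"targets": ["Entity"], "min": 0, "max": null, "site": true}
    },
    "Regulation": {
      "Theme": {"targets": ["Core_entity", "Regulon-operon", "Event"]},
      "Cause": {"targets": ["Core_entity", "Event"], "min": 0},
      "Site": {"targets": ["Entity"], "min": 0, "site": true},
      "CSite": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Positive_regulation": {
      "Theme": {"targets": ["Core_entity", "Regulon-operon", "Event"]},
      "Cause": {"targets": ["Core_entity", "Event"], "min": 0},
      "Site": {"targets": ["Entity"], "min": 0, "site": true},
      "CSite": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Negative_regulation": {
      "Theme": {"targets": ["Core_entity", "Regulon-operon", "Event"]},
      "Cause": {"targets": ["Core_entity", "Event"], "min": 0},
      "Site": {"targets": ["Entity"], "min": 0, "site": true},
      "CSite": {"targets": ["Entity"], "min": 0, "site": true}
    },
    "Process": {
      "Participant": {"targets": ["Core_entity"], "min": 0}
    }
  }
}
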