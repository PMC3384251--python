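{
  "name": "BI",
  "entity_types": {
    "Gene": "GeneEntity",
    "GeneComplex": "GeneEntity",
    "GeneFamily": "GeneEntity",
    "GeneProduct": "GeneEntity",
    "Protein": "ProteinEntity",
    "ProteinComplex": "ProteinEntity",
    "ProteinFamily": "ProteinEntity",
    "PolymeraseComplex": "ProteinEntity",
    "Regulon": null,
    "Site": null,
    "Promoter": null,
    "Transcription": null,
    "Expression": null,
    "Action": null
  },
  "given_types": [
    "Gene", "GeneComplex", "GeneFamily", "GeneProduct",
    "Protein", "ProteinComplex", "ProteinFamily", "PolymeraseComplex",
    "Regulon", "Site", "Promoter", "Transcription", "Expression", "Action"
  ],
  "site_mode": "protein-linked",
  "resolve_equiv": false,
  "relation_types": {
    "RegulonDependence": {
      "Regulon": {"targets": ["Regulon"]},
      "Target": {"targets": ["GeneEntity", "ProteinEntity"]}
    },
    "BindTo": {
      "Agent": {"targets": ["ProteinEntity"]},
      "Target": {"targets": ["Site", "Promoter", "Gene", "GeneComplex"]}
    },
    "TranscriptionFrom": {
      "Transcription": {"targets": ["Transcription", "Expression"]},
      "Site": {"targets": ["Site", "Promoter"]}
    },
    "RegulonMember": {
      "Regulon": {"targets": ["Regulon"]},
      "Member": {"targets": ["GeneEntity", "ProteinEntity"]}
    },
    "SiteOf": {
      "Site": {"targets": ["Site"]},
      "Entity": {"targets": ["Site", "Promoter", "GeneEntity"]}
    },
    "TranscriptionBy": {
      "Transcription": {"targets": ["Transcription"]},
      "Agent": {"targets": ["ProteinEntity"]}
    },
    "PromoterOf": {
      "Promoter": {"targets": ["Promoter"]},
      "Gene": {"targets": ["GeneEntity", "ProteinEntity"]}
    },
    "PromoterDependence": {
      "Promoter": {"targets": ["Promoter"]},
      "Protein": {"targets": ["GeneEntity", "ProteinEntity"]}
    },
    "ActionTarget": {
      "Action": {"targets": ["Action", "Expression", "Transcription"]},
      "Target": {"targets": ["*"]}
    },
    "Interaction": {
      "Agent": {"targets": ["GeneEntity", "ProteinEntity"]},
      "Target": {"targets": ["GeneEntity", "ProteinEntity"]}
    }
  }
}
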