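{
  "name": "REL",
  "entity_types": {"Protein": null, "Entity": null},
  "given_types": ["Protein"],
  "site_mode": "protein-linked",
  "resolve_equiv": false,
  "relation_types": {
    "Protein-Component": {
      "Arg1": {"targets": ["Protein"]},
      "Arg2": {"targets": ["Entity"]}
    },
    "Subunit-Complex": {
      "Arg1": {"targets": ["Protein"]},
      "Arg2": {"targets": ["Entity"]}
    }
  }
}
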