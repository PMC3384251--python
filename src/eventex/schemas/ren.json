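{
  "name": "REN",
  "entity_types": {"Gene": null},
  "given_types": ["Gene"],
  "site_mode": "protein-linked",
  "resolve_equiv": false,
  "undirected_relation_types": ["Renaming"],
  "relation_types": {
    "Renaming": {
      "Former": {"targets": ["Gene"]},
      "New": {"targets": ["Gene"]}
    }
  }
}
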