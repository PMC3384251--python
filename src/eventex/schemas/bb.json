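{
  "name": "BB",
  "entity_types": {
    "Bacterium": null,
    "Host": "Localization_site",
    "HostPart": "Localization_site",
    "Geographical": "Localization_site",
    "Environmental": "Localization_site",
    "Food": "Localization_site",
    "Medical": "Localization_site",
    "Soil": "Localization_site",
    "Water": "Localization_site"
  },
  "given_types": [],
  "site_mode": "protein-linked",
  "resolve_equiv": true,
  "relation_types": {
    "Localization": {
      "Bacterium": {"targets": ["Bacterium"]},
      "Localization": {"targets": ["Host", "HostPart", "Geographical", "Environmental", "Food", "Medical", "Soil", "Water"]}
    },
    "PartOf": {
      "HostPart": {"targets": ["HostPart"]},
      "Host": {"targets": ["Host"]}
    }
  }
}
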