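{
  "description": "Example path-model declaration: direct and indirect drivers of community mean pollinator specialization.",
  "nodes": ["MAT", "log_flower_abundance", "flower_richness", "mean_dprime_pollinator"],
  "mandatory_edges": [
    ["MAT", "flower_richness"],
    ["log_flower_abundance", "flower_richness"]
  ],
  "optional_edges": [
    ["MAT", "mean_dprime_pollinator"],
    ["flower_richness", "mean_dprime_pollinator"]
  ],
  "group": "site_id",
  "hypothesis_blocks": {
    "resources": ["log_flower_abundance", "flower_richness"],
    "pollinators": ["pollinator_richness", "visitation_rate"],
    "temperature": ["MAT", "ACT"],
    "area": ["area"]
  }
}
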