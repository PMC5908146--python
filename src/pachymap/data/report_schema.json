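{
  "type": "object",
  "required": ["version", "parameters", "image", "census", "metrics",
               "integration", "dynamics", "immunostaining"],
  "properties": {
    "version": {"type": "string"},
    "parameters": {
      "type": "object",
      "required": ["seed", "window_um", "min_prominence_rel",
                   "merge_window_um", "smooth_sigma_um", "k_sd", "alpha"]
    },
    "image": {
      "type": "object",
      "required": ["chromosome", "true_length_um", "straightened_length_um",
                   "true_centromere_um", "centromere_fish_um",
                   "centromere_constriction_um"]
    },
    "census": {"type": "object"},
    "metrics": {
      "type": "object",
      "required": ["levan", "compaction_cells_consistent",
                   "placements_consistent", "placements_flagged"]
    },
    "integration": {
      "type": "object",
      "required": ["pachytene_um", "linkage_cm", "somatic_um",
                   "pachytene_um_per_mb", "relative_lengths_pct"]
    },
    "dynamics": {
      "type": "object",
      "required": ["regions", "percent_reduction"]
    },
    "immunostaining": {
      "type": "object",
      "required": ["counterstain_peaks", "antibody_peaks", "matched"]
    }
  }
}
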