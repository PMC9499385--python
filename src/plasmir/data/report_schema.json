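{
  "type": "object",
  "required": ["config", "config_hash", "seed", "stages"],
  "properties": {
    "config": {"type": "object"},
    "config_hash": {"type": "string"},
    "seed": {"type": "integer"},
    "stages": {
      "type": "object",
      "properties": {
        "synth": {
          "type": "object",
          "required": ["n_samples", "n_mirnas"],
          "properties": {
            "n_samples": {"type": "integer"},
            "n_mirnas": {"type": "integer"},
            "n_degenerate": {"type": "integer"}
          }
        },
        "sample_qc": {
          "type": "object",
          "required": ["n_input", "n_retained", "exclusions"],
          "properties": {
            "n_input": {"type": "integer"},
            "n_retained": {"type": "integer"},
            "exclusions": {"type": "array"}
          }
        },
        "filtering": {
          "type": "object",
          "required": ["n_after_noise_filter", "n_analysis_mirnas"]
        },
        "profiles": {
          "type": "object",
          "required": ["mean_shannon", "mean_detected"],
          "properties": {
            "mean_shannon": {"type": "number"},
            "mean_detected": {"type": "number"}
          }
        },
        "hemoscore": {"type": "object"},
        "diffexpr": {
          "type": "object",
          "required": ["n_contrasts", "n_de_mirnas", "de_mirnas"],
          "properties": {
            "n_contrasts": {"type": "integer"},
            "n_de_mirnas": {"type": "integer"},
            "de_mirnas": {"type": "array"}
          }
        },
        "qpcr": {
          "type": "object",
          "required": ["n_retained", "exclusions"]
        }
      }
    }
  }
}
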