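{
  "type": "object",
  "required": ["config", "degs", "coupling", "independence"],
  "properties": {
    "config": {
      "type": "object",
      "required": ["deg_method", "deg_threshold", "seed"],
      "properties": {
        "deg_method": {"type": "string"},
        "deg_threshold": {"type": "number"},
        "seed": {"type": "integer"},
        "n_permutations": {"type": "integer"},
        "n_bootstrap": {"type": "integer"},
        "notes": {"type": "array", "items": {"type": "string"}}
      }
    },
    "prep": {
      "type": "object",
      "properties": {
        "n_features_in": {"type": "integer"},
        "n_low_signal_removed": {"type": "integer"},
        "n_genes": {"type": "integer"}
      }
    },
    "degs": {
      "type": "object",
      "required": ["transcriptome", "translatome"],
      "properties": {
        "transcriptome": {
          "type": "object",
          "required": ["n_significant"],
          "properties": {
            "n_significant": {"type": "integer"},
            "n_up": {"type": "integer"},
            "n_down": {"type": "integer"}
          }
        },
        "translatome": {
          "type": "object",
          "required": ["n_significant"],
          "properties": {
            "n_significant": {"type": "integer"},
            "n_up": {"type": "integer"},
            "n_down": {"type": "integer"}
          }
        }
      }
    },
    "coupling": {
      "type": "object",
      "required": ["counts", "n_degs"],
      "properties": {
        "counts": {
          "type": "object",
          "required": ["coupled", "antidirectional", "transcriptome_only", "translatome_only", "unchanged"],
          "properties": {
            "coupled": {"type": "integer"},
            "antidirectional": {"type": "integer"},
            "transcriptome_only": {"type": "integer"},
            "translatome_only": {"type": "integer"},
            "unchanged": {"type": "integer"}
          }
        },
        "n_degs": {"type": "integer"},
        "percent_uncoupled": {"type": ["number", "null"]}
      }
    },
    "buffering": {
      "type": "object",
      "properties": {
        "enhanced": {"type": "integer"},
        "buffered": {"type": "integer"},
        "tied": {"type": "integer"}
      }
    },
    "enrichment": {
      "type": ["object", "null"],
      "properties": {
        "transcriptome_enriched_terms": {"type": "array", "items": {"type": "string"}},
        "translatome_enriched_terms": {"type": "array", "items": {"type": "string"}},
        "overlap": {"type": "object"}
      }
    },
    "semantics": {
      "type": ["object", "null"],
      "properties": {
        "m": {"type": "integer"},
        "n": {"type": "integer"},
        "translatome_specificity": {"type": ["number", "null"]},
        "transcriptome_specificity": {"type": ["number", "null"]},
        "reason": {"type": ["string", "null"]}
      }
    },
    "independence": {
      "type": ["object", "null"],
      "properties": {
        "N": {"type": "integer"},
        "n1": {"type": "integer"},
        "n2": {"type": "integer"},
        "k": {"type": "integer"},
        "lrt_stat": {"type": "number"},
        "lrt_p": {"type": "number"},
        "overlap_p": {"type": "number"},
        "overlap_p_exact": {"type": "number"},
        "mi_observed": {"type": "number"},
        "mi_min": {"type": "number"},
        "mi_max": {"type": "number"},
        "mi_midrange_position": {"type": ["number", "null"]},
        "mi_p": {"type": "number"}
      }
    },
    "skipped": {"type": "array", "items": {"type": "string"}}
  }
}
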