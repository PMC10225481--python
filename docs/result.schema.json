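{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "oriseek result.json",
  "type": "object",
  "required": ["tool", "run", "records", "predictions", "terminus", "strand_bias", "warnings"],
  "properties": {
    "tool": {"const": "oriseek"},
    "run": {
      "type": "object",
      "properties": {
        "seed": {"type": "integer"},
        "config_sha256": {"type": "string"},
        "config": {"type": "object"}
      }
    },
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "length", "topology", "n_features", "source"],
        "properties": {
          "id": {"type": "string"},
          "length": {"type": "integer", "minimum": 1},
          "topology": {"enum": ["circular", "linear"]},
          "n_features": {"type": "integer", "minimum": 0},
          "source": {"enum": ["genbank", "fasta", "simulated"]}
        }
      }
    },
    "predictions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["record_id", "rank", "start", "end", "length", "total",
                     "s_dist", "s_gene", "s_box", "elements"],
        "properties": {
          "record_id": {"type": "string"},
          "rank": {"type": "integer", "minimum": 1},
          "start": {"type": "integer", "minimum": 1,
                    "description": "1-based inclusive"},
          "end": {"type": "integer", "minimum": 1},
          "wraps_origin": {"type": "boolean"},
          "length": {"type": "integer", "minimum": 1},
          "total": {"type": "number", "minimum": 0, "maximum": 3},
          "s_dist": {"type": "number", "minimum": 0, "maximum": 1},
          "s_gene": {"type": "number", "minimum": 0, "maximum": 1},
          "s_box": {"type": "number", "minimum": 0, "maximum": 1},
          "n_dnaa_boxes": {"type": "integer"},
          "n_trios": {"type": "integer"},
          "gatc_count": {"type": "integer"},
          "at_fraction": {"type": "number"},
          "left_gene": {"type": "string"},
          "right_gene": {"type": "string"},
          "elements": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["name", "start", "end", "strand", "score"],
              "properties": {
                "name": {"type": "string"},
                "start": {"type": "integer", "minimum": 1},
                "end": {"type": "integer", "minimum": 1},
                "strand": {"enum": ["+", "-"]},
                "score": {"type": "integer"}
              }
            }
          }
        }
      }
    },
    "terminus": {
      "type": ["object", "null"],
      "required": ["position", "method"],
      "properties": {
        "position": {"type": "integer", "minimum": 1},
        "method": {"enum": ["dif", "gc_max"]},
        "dif_mismatches": {"type": ["integer", "null"]}
      }
    },
    "strand_bias": {
      "type": ["object", "null"],
      "properties": {
        "arc1_frac": {"type": "number"},
        "arc2_frac": {"type": "number"},
        "leading_genes": {"type": "integer"},
        "lagging_genes": {"type": "integer"},
        "leading_gene_frac": {"type": "number"},
        "leading_base_pct": {"type": "object"},
        "lagging_base_pct": {"type": "object"}
      }
    },
    "warnings": {"type": "array", "items": {"type": "string"}}
  }
}
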