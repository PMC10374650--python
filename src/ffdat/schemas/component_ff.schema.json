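{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ffdat component force field",
  "type": "object",
  "required": ["format", "version", "name", "unit_profile", "sites", "terms", "exclusions"],
  "properties": {
    "format": {"const": "ffdat-component-ff"},
    "version": {"type": "integer"},
    "name": {"type": "string"},
    "unit_profile": {"type": "string"},
    "sites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["index", "tag", "id1", "params", "charge", "ref"],
        "properties": {
          "index": {"type": "integer", "minimum": 0},
          "tag": {"type": "string", "pattern": "^[^-]+-[^-]+-[0-9]+-[0-9]+$"},
          "id1": {"type": "integer", "minimum": 1},
          "params": {"type": "array", "items": {"type": "number"}},
          "charge": {"type": "number"},
          "ref": {"type": "string"}
        }
      }
    },
    "terms": {
      "type": "object",
      "required": ["bond", "angle", "torsion", "improper", "one_n", "special"],
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["kind", "sites", "orders", "function_id", "params", "ref"],
          "properties": {
            "kind": {"enum": ["bond", "angle", "torsion", "improper", "one_n", "special"]},
            "sites": {"type": "array", "items": {"type": "integer", "minimum": 0}},
            "orders": {"type": "array", "items": {"type": "integer", "minimum": 1}},
            "function_id": {"type": ["integer", "null"]},
            "params": {"type": "array", "items": {"type": "number"}},
            "ref": {"type": "string"},
            "separation": {"type": "integer", "minimum": 2},
            "scaling_vdw": {"type": "number", "minimum": 0, "maximum": 1},
            "scaling_elec": {"type": "number", "minimum": 0, "maximum": 1}
          }
        }
      }
    },
    "exclusions": {
      "type": "array",
      "items": {"type": "array", "items": {"type": "integer"}, "minItems": 3, "maxItems": 3}
    },
    "notes": {"type": "array", "items": {"type": "string"}}
  }
}
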