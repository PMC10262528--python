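{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "frailtykit deficit catalog",
  "type": "object",
  "required": ["name", "version", "deficits"],
  "properties": {
    "name": {"type": "string"},
    "version": {"type": "string"},
    "deficits": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "label", "system", "kind", "variant_class"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "label": {"type": "string"},
          "system": {"type": "string"},
          "kind": {"enum": ["binary", "ordinal", "threshold"]},
          "variant_class": {"enum": ["physical", "cognitive"]},
          "source": {"enum": ["column", "medication", "polypharmacy"]},
          "n_levels": {"type": "integer", "minimum": 2},
          "threshold": {"type": "number"},
          "direction": {"enum": ["above", "below"]}
        },
        "allOf": [
          {"if": {"properties": {"kind": {"const": "ordinal"}}}, "then": {"required": ["n_levels"]}},
          {"if": {"properties": {"kind": {"const": "threshold"}}}, "then": {"required": ["threshold", "direction"]}}
        ]
      }
    },
    "medication_map": {
      "type": "object",
      "additionalProperties": {"type": "string"},
      "description": "medication-class code -> condition deficit id"
    }
  }
}
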