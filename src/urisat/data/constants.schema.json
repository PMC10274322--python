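{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "urisat-constants-v1",
  "title": "urisat thermodynamic constants registry",
  "type": "object",
  "required": ["format", "species", "complexes", "salts"],
  "properties": {
    "format": {"const": "urisat-constants-v1"},
    "name": {"type": "string"},
    "version": {"type": "integer"},
    "reference_temperature": {"type": "number", "description": "degrees Celsius"},
    "species": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "charge"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "charge": {"type": "integer"},
          "component": {"type": "boolean", "default": false},
          "provenance": {"type": "string"}
        },
        "additionalProperties": false
      }
    },
    "complexes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "stoich", "charge", "log_beta"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "stoich": {
            "type": "object",
            "minProperties": 1,
            "additionalProperties": {"type": "integer"}
          },
          "charge": {"type": "integer"},
          "log_beta": {"type": "number"},
          "provenance": {"type": "string"}
        },
        "additionalProperties": false
      }
    },
    "salts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "lattice", "log_ksp"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "lattice": {
            "type": "object",
            "minProperties": 1,
            "additionalProperties": {"type": "integer", "exclusiveMinimum": 0}
          },
          "log_ksp": {"type": "number"},
          "provenance": {"type": "string"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
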