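{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Coverage report",
  "description": "YAML coverage report of an EHR system's coverage of trial-relevant concepts: overall, per use case and per concept group, with structured vs free-text split.",
  "type": "object",
  "required": ["overall", "use_cases"],
  "additionalProperties": false,
  "properties": {
    "overall": { "$ref": "#/$defs/row" },
    "use_cases": {
      "type": "array",
      "items": {
        "allOf": [{ "$ref": "#/$defs/row" }],
        "required": ["groups"],
        "properties": {
          "groups": { "type": "array", "items": { "$ref": "#/$defs/row" } }
        }
      }
    }
  },
  "$defs": {
    "row": {
      "type": "object",
      "required": ["label", "concepts", "mapped", "mapped_pct", "structured", "structured_pct"],
      "properties": {
        "label": { "type": "string" },
        "concepts": { "type": "integer", "minimum": 0 },
        "mapped": { "type": "integer", "minimum": 0 },
        "mapped_pct": { "type": "integer", "minimum": 0, "maximum": 100 },
        "structured": { "type": "integer", "minimum": 0 },
        "structured_pct": { "type": "integer", "minimum": 0, "maximum": 100 },
        "groups": { "type": "array" }
      }
    }
  }
}
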