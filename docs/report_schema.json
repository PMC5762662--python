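{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "traitflux pipeline report",
  "type": "object",
  "required": ["config", "stages", "results"],
  "properties": {
    "config": {"type": "object"},
    "stages": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["status"],
        "properties": {
          "status": {"type": "string"},
          "error": {"type": "string"}
        }
      }
    },
    "results": {
      "type": "object",
      "properties": {
        "decomposition": {"type": "array", "items": {"type": "object"}},
        "ordination": {"type": "object"},
        "rlq": {"type": "object"},
        "models": {"type": "object"}
      }
    }
  }
}
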