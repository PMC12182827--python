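{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "fetalplan planning report",
  "type": "object",
  "required": ["schema_version", "success", "vessels", "timings_s", "warnings", "config"],
  "properties": {
    "schema_version": {"type": "string"},
    "success": {"type": "boolean"},
    "failure": {"type": ["string", "null"]},
    "landmarks": {"type": ["object", "null"]},
    "timings_s": {"type": "object", "additionalProperties": {"type": "number"}},
    "warnings": {"type": "array", "items": {"type": "string"}},
    "config": {"type": "object"},
    "vessels": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["status"],
        "properties": {
          "status": {"enum": ["planned", "skipped"]},
          "reason": {"type": "string"},
          "prescription": {
            "type": "object",
            "required": ["vessel", "mode", "center_mm", "normal", "read_dir", "phase_dir", "fov_mm", "thickness_mm", "frame"],
            "properties": {
              "vessel": {"type": "string"},
              "mode": {"enum": ["vessel", "spine-surrogate"]},
              "center_mm": {"type": "array", "minItems": 3, "maxItems": 3, "items": {"type": "number"}},
              "normal": {"type": "array", "minItems": 3, "maxItems": 3, "items": {"type": "number"}},
              "read_dir": {"type": "array", "minItems": 3, "maxItems": 3, "items": {"type": "number"}},
              "phase_dir": {"type": "array", "minItems": 3, "maxItems": 3, "items": {"type": "number"}},
              "fov_mm": {"type": "array", "minItems": 2, "maxItems": 2, "items": {"type": "number"}},
              "thickness_mm": {"type": "number", "exclusiveMinimum": 0},
              "frame": {"const": "RAS"}
            }
          }
        }
      }
    }
  }
}
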