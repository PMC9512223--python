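{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hipforce force result record",
  "type": "array",
  "items": {
    "type": "object",
    "required": [
      "subject_id",
      "ramp_deg",
      "engine",
      "quantity",
      "value",
      "unit",
      "frame_label",
      "phase_window"
    ],
    "additionalProperties": false,
    "properties": {
      "subject_id": {"type": "string"},
      "ramp_deg": {"type": "number", "minimum": 0, "maximum": 70},
      "engine": {"type": "string", "enum": ["mechanistic", "empirical"]},
      "quantity": {"type": "string"},
      "value": {"type": "number"},
      "unit": {"type": "string", "enum": ["N", "BW", "xBW", "deg"]},
      "frame_label": {
        "type": "string",
        "enum": ["internal", "grf_paper_frame", "jrf_paper_frame"]
      },
      "phase_window": {"type": "string", "pattern": "^0\\.30-0\\.60$"}
    }
  }
}
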