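{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "CultivationRunRecord",
  "description": "One fed-batch CHO cultivation run: run-level setpoints, 13 daily offline samples, QC flags and free-form metadata. Field names are reconstructed from the process description; the original database schema is not public.",
  "type": "object",
  "required": ["run_id", "condition", "samples", "flags", "metadata"],
  "properties": {
    "run_id": {"type": "string"},
    "condition": {
      "type": "object",
      "description": "The eight run-level process setpoints plus the pH-shift target.",
      "required": [
        "ph_setpoint", "do_setpoint", "vcd0", "glc_start", "gln_start",
        "glc_feed_target", "feed_start_day", "ph_shift_day", "ph_shift_value"
      ],
      "properties": {
        "ph_setpoint": {"type": "number", "minimum": 6.6, "maximum": 7.6},
        "do_setpoint": {"type": "number", "minimum": 20, "maximum": 100},
        "vcd0": {"type": "number", "exclusiveMinimum": 0},
        "glc_start": {"type": "number", "minimum": 0},
        "gln_start": {"type": "number", "minimum": 0},
        "glc_feed_target": {"type": "number", "minimum": 0},
        "feed_start_day": {"type": "integer", "enum": [-1, 1, 2, 3, 4, 5]},
        "ph_shift_day": {"type": "integer", "enum": [-1, 0, 1, 2, 3, 4, 5]},
        "ph_shift_value": {"type": "number", "minimum": 6.6, "maximum": 7.6}
      }
    },
    "samples": {
      "type": "array",
      "description": "Daily offline measurements, day 0 through day 12.",
      "minItems": 1,
      "maxItems": 13,
      "items": {
        "type": "object",
        "required": ["day", "vcd", "viability", "diameter", "glc", "gln", "lac", "titer"],
        "properties": {
          "day": {"type": "integer", "minimum": 0, "maximum": 12},
          "vcd": {"type": "number", "minimum": 0},
          "viability": {"type": "number", "minimum": 0, "maximum": 100},
          "diameter": {"type": "number", "minimum": 0},
          "glc": {"type": "number", "minimum": 0},
          "gln": {"type": "number", "minimum": 0},
          "lac": {"type": "number", "minimum": 0},
          "titer": {"type": "number", "minimum": 0},
          "flags": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "flags": {"type": "array", "items": {"type": "string"}},
    "metadata": {"type": "object"}
  }
}
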