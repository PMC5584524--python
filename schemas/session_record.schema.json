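{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SessionRecord",
  "description": "Persisted transcript of one hybrid-method elicitation session.",
  "type": "object",
  "required": [
    "schema_version", "session_id", "mode", "consent_given", "consent_timestamp",
    "demographics", "training_attempts", "seed_answer", "main_answer_history",
    "final_main_answer", "vas_certainty", "timings", "status"
  ],
  "properties": {
    "schema_version": {"const": 1},
    "session_id": {"type": "string"},
    "mode": {"enum": ["face_to_face", "distance"]},
    "consent_given": {"type": "boolean"},
    "consent_timestamp": {"type": ["number", "null"]},
    "demographics": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["kind", "value"],
        "properties": {
          "kind": {"enum": ["choice", "integer", "free_text"]},
          "value": {"type": ["string", "integer"]}
        }
      }
    },
    "training_attempts": {"type": "array", "items": {"$ref": "#/$defs/attempt"}},
    "seed_answer": {
      "oneOf": [
        {"type": "number"},
        {"type": "null"},
        {"$ref": "#/$defs/rawAnswer"}
      ]
    },
    "main_answer_history": {"type": "array", "items": {"$ref": "#/$defs/attempt"}},
    "final_main_answer": {
      "oneOf": [{"type": "null"}, {"$ref": "#/$defs/rawAnswer"}]
    },
    "vas_certainty": {"type": ["number", "null"], "minimum": 0, "maximum": 100},
    "timings": {
      "type": "object",
      "properties": {
        "training": {"type": "number", "minimum": 0},
        "questionnaire": {"type": "number", "minimum": 0},
        "total": {"type": "number", "minimum": 0}
      }
    },
    "status": {"enum": ["complete", "aborted", "draft"]}
  },
  "$defs": {
    "rawAnswer": {
      "type": "object",
      "required": ["L", "M", "H", "p"],
      "properties": {
        "L": {"type": "number"},
        "M": {"type": "number"},
        "H": {"type": "number"},
        "p": {"type": "array", "items": {"type": "number"}, "minItems": 4, "maxItems": 4}
      }
    },
    "attempt": {
      "type": "object",
      "required": ["answer", "report", "confirmed"],
      "properties": {
        "answer": {"$ref": "#/$defs/rawAnswer"},
        "confirmed": {"type": "boolean"},
        "report": {
          "type": "object",
          "required": ["overall_valid", "checks"],
          "properties": {
            "overall_valid": {"type": "boolean"},
            "checks": {
              "type": "array",
              "minItems": 4,
              "maxItems": 4,
              "items": {
                "type": "object",
                "required": ["rule_id", "severity", "passed", "message"],
                "properties": {
                  "rule_id": {"enum": ["TOTAL_PROB", "ORDERING", "NON_UNIFORM", "NOT_FULL_RANGE"]},
                  "severity": {"enum": ["error", "warning"]},
                  "passed": {"type": "boolean"},
                  "message": {"type": "string"}
                }
              }
            }
          }
        }
      }
    }
  }
}
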