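{
  "description": "Single-JSON summary of a QA run (validates against the shipped schema).",
  "properties": {
    "best_window": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Best Window"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "duty_cycle": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Duty Cycle"
    },
    "gpr_1mm1pct": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Gpr 1Mm1Pct"
    },
    "gpr_2mm2pct": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Gpr 2Mm2Pct"
    },
    "outputs": {
      "additionalProperties": {
        "type": "string"
      },
      "default": {},
      "title": "Outputs",
      "type": "object"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "versions": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Versions",
      "type": "object"
    }
  },
  "required": [
    "seed",
    "versions",
    "config"
  ],
  "title": "RunReport",
  "type": "object"
}
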