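{
  "$defs": {
    "SampleReport": {
      "additionalProperties": false,
      "properties": {
        "sample_id": {
          "title": "Sample Id",
          "type": "string"
        },
        "genotype": {
          "title": "Genotype",
          "type": "string"
        },
        "stages": {
          "$ref": "#/$defs/StageCountsReport"
        },
        "n_target": {
          "title": "N Target",
          "type": "integer"
        },
        "n_spike": {
          "title": "N Spike",
          "type": "integer"
        },
        "target_spike_ratio": {
          "title": "Target Spike Ratio",
          "type": "number"
        },
        "median_length": {
          "title": "Median Length",
          "type": "number"
        },
        "ts_nts_ratio": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Ts Nts Ratio"
        },
        "genome_distribution": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Genome Distribution",
          "type": "object"
        },
        "relative_repair_percent": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Relative Repair Percent"
        },
        "relative_repair_ci": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "number"
                },
                {
                  "type": "number"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Relative Repair Ci"
        }
      },
      "required": [
        "sample_id",
        "genotype",
        "stages",
        "n_target",
        "n_spike",
        "target_spike_ratio",
        "median_length",
        "ts_nts_ratio",
        "genome_distribution"
      ],
      "title": "SampleReport",
      "type": "object"
    },
    "StageCountsReport": {
      "additionalProperties": false,
      "properties": {
        "n_input": {
          "title": "N Input",
          "type": "integer"
        },
        "n_trimmed": {
          "title": "N Trimmed",
          "type": "integer"
        },
        "n_deduplicated": {
          "title": "N Deduplicated",
          "type": "integer"
        },
        "n_with_n_dropped": {
          "title": "N With N Dropped",
          "type": "integer"
        },
        "n_aligned_unique": {
          "title": "N Aligned Unique",
          "type": "integer"
        },
        "n_multi_hit": {
          "title": "N Multi Hit",
          "type": "integer"
        },
        "n_no_hit": {
          "title": "N No Hit",
          "type": "integer"
        },
        "n_filtered": {
          "title": "N Filtered",
          "type": "integer"
        }
      },
      "required": [
        "n_input",
        "n_trimmed",
        "n_deduplicated",
        "n_with_n_dropped",
        "n_aligned_unique",
        "n_multi_hit",
        "n_no_hit",
        "n_filtered"
      ],
      "title": "StageCountsReport",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Top-level machine-readable result bundle of ``xrseq report``.",
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "reference_sample": {
      "title": "Reference Sample",
      "type": "string"
    },
    "samples": {
      "items": {
        "$ref": "#/$defs/SampleReport"
      },
      "title": "Samples",
      "type": "array"
    }
  },
  "required": [
    "seed",
    "reference_sample",
    "samples"
  ],
  "title": "RunReport",
  "type": "object"
}
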