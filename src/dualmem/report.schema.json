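{
  "$defs": {
    "DeviationModel": {
      "properties": {
        "max_abs_dev": {
          "title": "Max Abs Dev",
          "type": "number"
        },
        "mean_abs_dev": {
          "title": "Mean Abs Dev",
          "type": "number"
        },
        "mean_signed_dev": {
          "title": "Mean Signed Dev",
          "type": "number"
        }
      },
      "required": [
        "mean_signed_dev",
        "mean_abs_dev",
        "max_abs_dev"
      ],
      "title": "DeviationModel",
      "type": "object"
    },
    "FitModel": {
      "properties": {
        "boundary": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Boundary"
        },
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "n_draws": {
          "default": 0,
          "title": "N Draws",
          "type": "integer"
        },
        "objective": {
          "minimum": 0,
          "title": "Objective",
          "type": "number"
        },
        "rho_hat": {
          "maximum": 1,
          "minimum": 0,
          "title": "Rho Hat",
          "type": "number"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        }
      },
      "required": [
        "rho_hat",
        "objective",
        "converged"
      ],
      "title": "FitModel",
      "type": "object"
    },
    "GroupBlockModel": {
      "properties": {
        "deviation_fitted": {
          "$ref": "#/$defs/DeviationModel"
        },
        "deviation_independent": {
          "$ref": "#/$defs/DeviationModel"
        },
        "efficacy_reduction": {
          "title": "Efficacy Reduction",
          "type": "number"
        },
        "fit": {
          "$ref": "#/$defs/FitModel"
        },
        "means": {
          "$ref": "#/$defs/MeansModel"
        },
        "pc_r_range_fraction_closed": {
          "maximum": 1,
          "minimum": 0,
          "title": "Pc R Range Fraction Closed",
          "type": "number"
        },
        "pc_r_range_fraction_open": {
          "maximum": 1,
          "minimum": 0,
          "title": "Pc R Range Fraction Open",
          "type": "number"
        }
      },
      "required": [
        "means",
        "deviation_independent",
        "fit",
        "deviation_fitted",
        "efficacy_reduction",
        "pc_r_range_fraction_closed",
        "pc_r_range_fraction_open"
      ],
      "title": "GroupBlockModel",
      "type": "object"
    },
    "MeansModel": {
      "properties": {
        "n": {
          "minimum": 1,
          "title": "N",
          "type": "integer"
        },
        "pc_r": {
          "maximum": 1,
          "minimum": 0,
          "title": "Pc R",
          "type": "number"
        },
        "pc_t": {
          "maximum": 1,
          "minimum": 0,
          "title": "Pc T",
          "type": "number"
        },
        "pc_t_pred": {
          "maximum": 1,
          "minimum": 0,
          "title": "Pc T Pred",
          "type": "number"
        },
        "te": {
          "title": "Te",
          "type": "number"
        },
        "te_pred": {
          "title": "Te Pred",
          "type": "number"
        }
      },
      "required": [
        "n",
        "pc_r",
        "pc_t",
        "pc_t_pred",
        "te",
        "te_pred"
      ],
      "title": "MeansModel",
      "type": "object"
    },
    "ProvenanceModel": {
      "properties": {
        "config_hash": {
          "minLength": 1,
          "title": "Config Hash",
          "type": "string"
        },
        "created": {
          "minLength": 1,
          "title": "Created",
          "type": "string"
        },
        "package": {
          "title": "Package",
          "type": "string"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "package",
        "version",
        "config_hash",
        "created"
      ],
      "title": "ProvenanceModel",
      "type": "object"
    },
    "TestResultModel": {
      "properties": {
        "bf01": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bf01"
        },
        "bf10": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bf10"
        },
        "df": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            }
          ],
          "title": "Df"
        },
        "effect_size": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Effect Size"
        },
        "evidence_label": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Evidence Label"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "statistic": {
          "title": "Statistic",
          "type": "number"
        }
      },
      "required": [
        "statistic",
        "df",
        "p_value"
      ],
      "title": "TestResultModel",
      "type": "object"
    }
  },
  "description": "Full analysis output; see module docstring for the stage order.",
  "properties": {
    "anova_data_type": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/TestResultModel"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Anova Data Type"
    },
    "anova_training_task": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/TestResultModel"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Anova Training Task"
    },
    "groups": {
      "additionalProperties": {
        "$ref": "#/$defs/GroupBlockModel"
      },
      "title": "Groups",
      "type": "object"
    },
    "model": {
      "title": "Model",
      "type": "string"
    },
    "notes": {
      "items": {
        "type": "string"
      },
      "title": "Notes",
      "type": "array"
    },
    "provenance": {
      "$ref": "#/$defs/ProvenanceModel"
    },
    "rho": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Rho"
    },
    "t_data_type": {
      "additionalProperties": {
        "$ref": "#/$defs/TestResultModel"
      },
      "title": "T Data Type",
      "type": "object"
    }
  },
  "required": [
    "provenance",
    "model",
    "groups"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
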