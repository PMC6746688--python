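{
  "$defs": {
    "CalibrationModel": {
      "additionalProperties": false,
      "properties": {
        "endpoint_a": {
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
          "title": "Endpoint A",
          "type": "array"
        },
        "endpoint_b": {
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
          "title": "Endpoint B",
          "type": "array"
        },
        "known_length_cm": {
          "default": 2.0,
          "exclusiveMinimum": 0,
          "title": "Known Length Cm",
          "type": "number"
        }
      },
      "required": [
        "endpoint_a",
        "endpoint_b"
      ],
      "title": "CalibrationModel",
      "type": "object"
    },
    "PhotoBlockModel": {
      "additionalProperties": false,
      "properties": {
        "calibration": {
          "$ref": "#/$defs/CalibrationModel"
        },
        "height_px": {
          "anyOf": [
            {
              "exclusiveMinimum": 0,
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Height Px"
        },
        "image_path": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Image Path"
        },
        "landmarks": {
          "additionalProperties": {
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
          "title": "Landmarks",
          "type": "object"
        },
        "photo_id": {
          "title": "Photo Id",
          "type": "string"
        },
        "role": {
          "pattern": "^(primary|secondary)$",
          "title": "Role",
          "type": "string"
        },
        "width_px": {
          "anyOf": [
            {
              "exclusiveMinimum": 0,
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Width Px"
        }
      },
      "required": [
        "photo_id",
        "role",
        "calibration",
        "landmarks"
      ],
      "title": "PhotoBlockModel",
      "type": "object"
    },
    "SubjectModel": {
      "additionalProperties": false,
      "properties": {
        "id": {
          "title": "Id",
          "type": "string"
        },
        "notes": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Notes"
        },
        "sex_type": {
          "anyOf": [
            {
              "pattern": "^(female|male)$",
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sex Type"
        }
      },
      "required": [
        "id"
      ],
      "title": "SubjectModel",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Top-level annotation document.",
  "properties": {
    "photos": {
      "items": {
        "$ref": "#/$defs/PhotoBlockModel"
      },
      "maxItems": 2,
      "minItems": 1,
      "title": "Photos",
      "type": "array"
    },
    "schema_version": {
      "title": "Schema Version",
      "type": "integer"
    },
    "subject": {
      "$ref": "#/$defs/SubjectModel"
    }
  },
  "required": [
    "schema_version",
    "subject",
    "photos"
  ],
  "title": "AnnotationFileModel",
  "type": "object"
}
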