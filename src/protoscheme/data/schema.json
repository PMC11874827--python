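{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "protoscheme/schema.json",
  "title": "Protein topology scheme document (Pfam domain-graphics dialect), version 1",
  "description": "Normative structural description of the scheme JSON emitted and accepted by protoscheme. The executable equivalent is protoscheme.codec.validate_document.",
  "type": "object",
  "required": ["length", "regions", "motifs", "markups"],
  "properties": {
    "length": {"type": "integer", "minimum": 1, "description": "Protein length in amino acids."},
    "metadata": {
      "type": "object",
      "properties": {
        "name": {"type": "string"},
        "accession": {"type": "string"}
      }
    },
    "regions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["start", "end", "text", "colour", "startStyle", "endStyle"],
        "properties": {
          "start": {"type": "integer", "minimum": 1},
          "end": {"type": "integer", "minimum": 1},
          "text": {"type": "string"},
          "colour": {"type": "string", "pattern": "^#[0-9A-Fa-f]{6}$"},
          "startStyle": {"enum": ["curved", "straight", "jagged", "arrow"]},
          "endStyle": {"enum": ["curved", "straight", "jagged", "arrow"]},
          "metadata": {"$ref": "#/$defs/featureMetadata"}
        }
      }
    },
    "motifs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["start", "end", "colour"],
        "properties": {
          "start": {"type": "integer", "minimum": 1},
          "end": {"type": "integer", "minimum": 1},
          "colour": {"type": "string", "pattern": "^#[0-9A-Fa-f]{6}$"},
          "display": {"type": "boolean"},
          "opacity": {"type": "number", "minimum": 0, "maximum": 1},
          "metadata": {"$ref": "#/$defs/featureMetadata"}
        }
      }
    },
    "markups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["start", "colour", "headStyle"],
        "properties": {
          "start": {"type": "integer", "minimum": 1},
          "lineColour": {"type": "string", "pattern": "^#[0-9A-Fa-f]{6}$"},
          "colour": {"type": "string", "pattern": "^#[0-9A-Fa-f]{6}$"},
          "headStyle": {"enum": ["circle", "square", "diamond", "arrow", "pentagon", "line"]},
          "metadata": {"$ref": "#/$defs/featureMetadata"}
        }
      }
    }
  },
  "$defs": {
    "featureMetadata": {
      "type": "object",
      "description": "Lossless-decoding extension: provenance and canonical type of the feature.",
      "properties": {
        "label": {"type": "string"},
        "type": {"type": "string"},
        "source": {"type": "string"},
        "score": {"type": "number"}
      }
    }
  }
}
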