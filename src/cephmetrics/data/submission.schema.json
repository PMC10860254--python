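{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Cephalometric submission export",
  "description": "One student's tracing of one lateral cephalogram as exported by the tracing application. Coordinates are pixels in the y-down image frame; timestamps are ISO-8601.",
  "type": "object",
  "required": ["image", "device", "landmarks"],
  "properties": {
    "version": {"type": "integer"},
    "name": {"type": "string", "description": "Plain name or pseudonym of the student."},
    "image": {
      "type": "object",
      "required": ["id"],
      "properties": {
        "id": {"type": "string", "description": "Cephalogram identifier (A or B in the study)."},
        "source": {"enum": ["dicom", "screenshot"]}
      }
    },
    "device": {"enum": ["tablet", "desktop"]},
    "order": {"enum": [0, 1], "description": "0 if this is the student's first analysis."},
    "gender": {"enum": ["female", "male", "unknown"]},
    "t_first": {"type": "string", "format": "date-time"},
    "t_last": {"type": "string", "format": "date-time"},
    "landmarks": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "x", "y"],
        "properties": {
          "name": {"type": "string"},
          "x": {"type": "number"},
          "y": {"type": "number"},
          "t": {"type": "string", "format": "date-time"}
        }
      }
    }
  }
}
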