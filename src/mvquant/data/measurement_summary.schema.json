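{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "mvquant cycle summary",
  "type": "object",
  "required": ["n_frames", "peak_frame", "ea_mean_mm2", "ea_min_mm2", "ea_max_mm2"],
  "properties": {
    "n_frames": {"type": "integer", "minimum": 1},
    "peak_frame": {"type": "integer", "minimum": 0},
    "ea_mean_mm2": {"type": "number", "minimum": 0},
    "ea_min_mm2": {"type": "number", "minimum": 0},
    "ea_max_mm2": {"type": "number", "minimum": 0}
  }
}
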