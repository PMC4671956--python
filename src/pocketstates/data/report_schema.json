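{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pocketstates report",
  "type": "object",
  "required": ["kind"],
  "properties": {"kind": {"enum": ["structure", "ensemble", "trajectory", "benchmarks"]}},
  "oneOf": [
    {
      "properties": {"kind": {"const": "structure"}},
      "required": ["input", "chains", "halogen_bonds", "n_hydrogen_bonds"]
    },
    {
      "properties": {"kind": {"const": "ensemble"}},
      "required": ["n_structures", "metrics", "rotamer_tally"]
    },
    {
      "properties": {"kind": {"const": "trajectory"}},
      "required": ["n_frames", "populations_pct", "clusters", "frames"]
    },
    {
      "properties": {"kind": {"const": "benchmarks"}},
      "required": ["results", "available", "skipped"]
    }
  ]
}
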