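{
  "name": "udp_glcnac",
  "subunits": [
    {
      "name": "glucose",
      "carbon_count": 6,
      "allowed_labels": [0, 6],
      "parameter_names": ["g0", "g6"]
    },
    {
      "name": "ribose",
      "carbon_count": 5,
      "allowed_labels": [0, 5],
      "parameter_names": ["r0", "r5"]
    },
    {
      "name": "acetyl",
      "carbon_count": 2,
      "allowed_labels": [0, 2],
      "parameter_names": ["a0", "a2"]
    },
    {
      "name": "uracil",
      "carbon_count": 4,
      "allowed_labels": [0, 1, 2, 3],
      "parameter_names": ["u0", "u1", "u2", "u3"]
    }
  ]
}
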