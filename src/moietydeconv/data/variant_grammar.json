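{
  "glucose": [[0, 3, 6], [0, 1, 2, 3, 4, 5, 6]],
  "ribose": [[0, 2, 5]],
  "acetyl": [[0, 1, 2]],
  "uracil": [[0, 1, 2, 3, 4], [0, 1, 2], [0, 2, 3]]
}
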