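{
  "DdeI": {"recognition": "CTNAG", "cut_offset": 1},
  "XmnI": {"recognition": "GAANNNNTTC", "cut_offset": 5},
  "HindIII": {"recognition": "AAGCTT", "cut_offset": 1},
  "HincII": {"recognition": "GTYRAC", "cut_offset": 3},
  "HinfI": {"recognition": "GANTC", "cut_offset": 1}
}
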