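{
  "chothia": {
    "H": {"H1": [26, 32], "H2": [52, 56], "H3": [95, 102]},
    "L": {"L1": [24, 34], "L2": [50, 56], "L3": [89, 97]}
  },
  "kabat": {
    "H": {"H1": [31, 35], "H2": [50, 65], "H3": [95, 102]},
    "L": {"L1": [24, 34], "L2": [50, 56], "L3": [89, 97]}
  },
  "imgt": {
    "H": {"H1": [27, 38], "H2": [56, 65], "H3": [105, 117]},
    "L": {"L1": [27, 38], "L2": [56, 65], "L3": [105, 117]}
  }
}
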