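{
  "version": "1.0",
  "anchor_index": 50,
  "layouts": {
    "common": [
      {"name": "bA", "kind": "strand"},
      {"name": "aA", "kind": "helix"},
      {"name": "bB", "kind": "strand"},
      {"name": "bBbC", "kind": "turn"},
      {"name": "bC", "kind": "strand"},
      {"name": "bD", "kind": "strand"},
      {"name": "bE", "kind": "strand"},
      {"name": "bF", "kind": "strand"},
      {"name": "aB", "kind": "helix"}
    ],
    "STAT": [
      {"name": "bA", "kind": "strand"},
      {"name": "aA", "kind": "helix"},
      {"name": "bB", "kind": "strand"},
      {"name": "bBbC", "kind": "turn"},
      {"name": "bC", "kind": "strand"},
      {"name": "bD", "kind": "strand"},
      {"name": "aB'", "kind": "helix"},
      {"name": "aB", "kind": "helix"}
    ]
  },
  "index_spans": {
    "bA": [46, 52],
    "aA": [42, 54],
    "bB": [46, 52],
    "bBbC": [49, 50],
    "bC": [46, 54],
    "bD": [47, 53],
    "bE": [48, 52],
    "bF": [48, 52],
    "aB'": [45, 54],
    "aB": [44, 56]
  },
  "sheinerman_positions": [
    "aAx43", "aAx47", "bBx50", "bBx52",
    "bBbCx49", "bBbCx50", "bDx50", "bDx52"
  ],
  "flvr_exception_proteins": ["RIN2", "TYK2", "SH2D5"]
}
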