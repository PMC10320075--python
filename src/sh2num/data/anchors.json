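{
  "STAT5B": {
    "protein_id": "STAT5B",
    "domain_slot": "N",
    "layout": "STAT",
    "anchors": {"aA": [43, 600], "bB": [50, 618], "bBbC": [49, 621], "bD": [50, 642]},
    "segment_spans": {"aA": [42, 52], "bB": [46, 52], "bBbC": [49, 50], "bD": [47, 53]},
    "contiguous_segments": ["aA", "bB", "bBbC", "bD"]
  },
  "SHP2": {
    "protein_id": "SHP2",
    "domain_slot": "N",
    "layout": "common",
    "anchors": {"bE": [48, 62]},
    "segment_spans": {"bE": [48, 51]},
    "contiguous_segments": ["bE"]
  },
  "flvr_exceptions": ["RIN2", "TYK2", "SH2D5"]
}
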