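{
  "classes": {
    "aromatic": "FYW",
    "negative": "DE",
    "positive": "KR",
    "small_aliphatic": "GA",
    "larger_aliphatic": "VLIP",
    "hydrophilic": "STHNQCM"
  }
}
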