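{
  "name": "diabetes",
  "dias": ["eating", "sleeping", "movement", "toileting", "weight"],
  "pattern": ["very high", "very high", "very high", "very high", "very low"],
  "threshold": 0.9
}
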