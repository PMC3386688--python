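{
  "_note": "Synthetic stand-in pattern: the DIA list follows the usual depression signs (activity in mild illumination, staying in, sleep and appetite changes, weight loss) but the grade vector is a package-chosen illustration, not clinically validated.",
  "name": "depression",
  "dias": ["lighting", "going out", "sleeping", "eating", "weight"],
  "pattern": ["low", "very low", "low", "low", "low"],
  "threshold": 0.9
}
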