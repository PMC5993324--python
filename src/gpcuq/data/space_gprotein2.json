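[
 {
  "name": "kGa",
  "lo": 1e-07,
  "hi": 0.001,
  "scale": "log10"
 },
 {
  "name": "kGd",
  "lo": 0.001,
  "hi": 10.0,
  "scale": "log10"
 }
]
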