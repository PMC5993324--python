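[
 {
  "name": "kRL",
  "lo": 0.0002,
  "hi": 0.02,
  "scale": "log10"
 },
 {
  "name": "kRLm",
  "lo": 0.001,
  "hi": 0.1,
  "scale": "log10"
 },
 {
  "name": "kRs",
  "lo": 0.4,
  "hi": 40.0,
  "scale": "log10"
 },
 {
  "name": "kRd0",
  "lo": 4e-05,
  "hi": 0.004,
  "scale": "log10"
 },
 {
  "name": "kRd1",
  "lo": 4e-05,
  "hi": 0.004,
  "scale": "log10"
 },
 {
  "name": "kG1",
  "lo": 0.1,
  "hi": 10.0,
  "scale": "log10"
 },
 {
  "name": "kGa",
  "lo": 1.0000000000000002e-06,
  "hi": 0.0001,
  "scale": "log10"
 },
 {
  "name": "kGd",
  "lo": 0.01,
  "hi": 1.0,
  "scale": "log10"
 }
]
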