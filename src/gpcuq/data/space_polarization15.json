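[
 {
  "name": "D_C42",
  "lo": 0.005,
  "hi": 0.02,
  "scale": "log10"
 },
 {
  "name": "D_C42a",
  "lo": 0.005,
  "hi": 0.02,
  "scale": "log10"
 },
 {
  "name": "k42d",
  "lo": 0.02,
  "hi": 2.0,
  "scale": "log10"
 },
 {
  "name": "k42a",
  "lo": 0.00012566370614359174,
  "hi": 0.012566370614359173,
  "scale": "log10"
 },
 {
  "name": "k24cm0",
  "lo": 0.004,
  "hi": 0.4,
  "scale": "log10"
 },
 {
  "name": "k24cm1",
  "lo": 0.004146902302738527,
  "hi": 0.4146902302738527,
  "scale": "log10"
 },
 {
  "name": "kB1mc",
  "lo": 0.01,
  "hi": 1.0,
  "scale": "log10"
 },
 {
  "name": "kB1cm",
  "lo": 0.00012566370614359174,
  "hi": 0.012566370614359173,
  "scale": "log10"
 },
 {
  "name": "kCla4a",
  "lo": 0.0006,
  "hi": 0.06,
  "scale": "log10"
 },
 {
  "name": "kCla4d",
  "lo": 0.001,
  "hi": 0.1,
  "scale": "log10"
 },
 {
  "name": "k24d",
  "lo": 0.00041887902047863906,
  "hi": 0.041887902047863905,
  "scale": "log10"
 },
 {
  "name": "q",
  "lo": 1.0,
  "hi": 100.0,
  "scale": "linear"
 },
 {
  "name": "h",
  "lo": 1.0,
  "hi": 8.0,
  "scale": "linear"
 },
 {
  "name": "C24t",
  "lo": 1000.0,
  "hi": 3000.0,
  "scale": "log10"
 },
 {
  "name": "B1t",
  "lo": 2000.0,
  "hi": 5000.0,
  "scale": "log10"
 }
]
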