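[
 {
  "name": "D_R",
  "lo": 0.0009000000000000001,
  "hi": 0.0011,
  "scale": "log10"
 },
 {
  "name": "D_RL",
  "lo": 0.0009000000000000001,
  "hi": 0.0011,
  "scale": "log10"
 },
 {
  "name": "D_G",
  "lo": 0.005,
  "hi": 0.02,
  "scale": "log10"
 },
 {
  "name": "D_Ga",
  "lo": 0.005,
  "hi": 0.02,
  "scale": "log10"
 },
 {
  "name": "D_Gbg",
  "lo": 0.005,
  "hi": 0.02,
  "scale": "log10"
 },
 {
  "name": "D_Gd",
  "lo": 0.005,
  "hi": 0.02,
  "scale": "log10"
 },
 {
  "name": "D_C24m",
  "lo": 0.005,
  "hi": 0.02,
  "scale": "log10"
 },
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
  "name": "D_B1m",
  "lo": 0.005,
  "hi": 0.02,
  "scale": "log10"
 },
 {
  "name": "kRL",
  "lo": 0.0018000000000000002,
  "hi": 0.0022,
  "scale": "log10"
 },
 {
  "name": "kRLm",
  "lo": 0.009000000000000001,
  "hi": 0.011000000000000001,
  "scale": "log10"
 },
 {
  "name": "kRd0",
  "lo": 0.00036,
  "hi": 0.00044000000000000007,
  "scale": "log10"
 },
 {
  "name": "kRd1",
  "lo": 0.00036,
  "hi": 0.00044000000000000007,
  "scale": "log10"
 },
 {
  "name": "kRs",
  "lo": 0.2864788975654116,
  "hi": 0.35014087480216977,
  "scale": "log10"
 },
 {
  "name": "kGa",
  "lo": 0.00011309733552923256,
  "hi": 0.00013823007675795092,
  "scale": "log10"
 },
 {
  "name": "kGd",
  "lo": 0.09000000000000001,
  "hi": 0.11000000000000001,
  "scale": "log10"
 },
 {
  "name": "kG1",
  "lo": 0.9,
  "hi": 1.1,
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
  "name": "k24mc",
  "lo": 0.1,
  "hi": 1.0,
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
 },
 {
  "name": "Rt",
  "lo": 9000.0,
  "hi": 11000.0,
  "scale": "log10"
 },
 {
  "name": "Gt",
  "lo": 9000.0,
  "hi": 11000.0,
  "scale": "log10"
 },
 {
  "name": "C42t",
  "lo": 5000.0,
  "hi": 20000.0,
  "scale": "log10"
 }
]
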