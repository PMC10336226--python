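# Seed-averaged sweep of the train-offset for the inverted-standard
# protocol (2 nA, 1 ms width, 83 Hz cycle).
base:
  duration: 15000.0
  seizure:
    amplitude: 200.0
    start: 1000.0
    duration: 3000.0
grid:
  protocols: [inverted-standard]
  amplitudes: [2.0]
  train_offsets: [-2.0, -1.0, -0.5, 0.0, 0.5, 1.0]
  seeds: [0, 1, 2, 3, 4]
protocol_onset: 10000.0
protocol_duration: 5000.0
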