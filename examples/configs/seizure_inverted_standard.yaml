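# Standard seizure experiment with the optimal weight-increasing protocol:
# induction at 1 s (200 pA, 3 s, central 50 E neurons), inverted-standard
# FTSTS at 10 s for 5 s, published pulse settings.
duration: 16000.0
seed: 1
seizure:
  amplitude: 200.0
  start: 1000.0
  duration: 3000.0
electrical:
  - name: inverted-standard
    amplitude: 2.0
    width: 1.0
    inter_pulse_interval: 10.0
    train_offset: -0.5
    onset: 10000.0
    duration: 5000.0
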