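"""Inspect the four FTSTS polarity pairs and their charge balance.

Prints the first cycle of the excitatory- and inhibitory-population
pulse trains for each named protocol and verifies the zero-net-charge
property that makes the pulses safe for chronic delivery.
"""

import numpy as np

from ftsts import PROTOCOL_POLARITIES, ProtocolSpec, build_pulse_train

t = np.arange(0.0, 24.0, 0.5)
for name in PROTOCOL_POLARITIES:
    proto = ProtocolSpec(name=name, onset=0.0, duration=24.0)
    w_e = build_pulse_train(proto.train("E"), t, 0.0)
    w_i = build_pulse_train(proto.train("I"), t, proto.train_offset)
    print(f"{name} (a_E={proto.a_E:+d}, a_I={proto.a_I:+d})")
    print("  E train (nA), first cycle:", w_e[:26])
    print("  I train (nA), first cycle:", w_i[:26])
    print(f"  net charge over the train: {w_e.sum() * 0.5:+.1e} nA*ms")

print("\nEach biphasic pulse is two contiguous 1 ms phases of +-2 nA "
      "(order set by the polarity), then 10 ms of rest: a 12 ms cycle "
      "(83 Hz).  Every train integrates to exactly zero charge.")
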