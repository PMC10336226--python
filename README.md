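# ftsts

Simulation and protocol-design toolkit for **forced temporal spike-time
stimulation (FTSTS)** of epileptic networks: a spiking excitatory-
inhibitory (E-I) neocortical seizure model plus generators for the paired
charge-balanced biphasic pulse trains (electrical) and two-color
channelrhodopsin light schedules (optogenetic) that steer the network's
excitatory-to-inhibitory synaptic weights through spike-timing-dependent
plasticity (STDP).

It is written for computational neuroscientists and neurostimulation
engineers who want to explore how pulse polarity, amplitude, width,
frequency and especially the **train-offset time** between the two
population-specific pulse trains determine whether a stimulation protocol
potentiates or depresses the E->I pathway — and hence whether it
suppresses or promotes seizures.

## Model in brief

500 excitatory + 500 inhibitory stochastic conductance-based
integrate-and-fire neurons on a line, with distance-dependent Gaussian
connectivity (row sums conserved: W0_EE = 104, W0_EI = 100, W0_II =
W0_IE = 250 nS plus a weak uniform inhibitory synapse):

- membrane: C dV/dt = g_L(E_L-V) + f_max[g_E(E_E-V) + g_I(E_Cl-V) + g_K(E_K-V)] + I_app
- spiking: inhomogeneous Poisson, f = f0 exp((V-phi)/beta), adaptive
  threshold phi, 5 ms refractory period
- chloride-dependent GABA reversal E_Cl = -26.7 ln([Cl_out]/[Cl_in]) with
  activity-dependent chloride loading (seizures collapse inhibition)
- trace-based Hebbian STDP on E->E and E->I synapses: pre-before-post at
  lag dt changes the plastic fraction by +eta A0 e^(-dt/tau_STDP),
  post-before-pre by the negative

An FTSTS protocol delivers one biphasic pulse train per population
(polarity +-1 = starts with its negative/positive phase; 2 nA, 1 ms
phases, 12 ms cycle by default).  The positive phase forces spikes and
the negative phase suppresses them, so the two trains impose a relative
E/I spike ordering which STDP converts into a directed change of the
average E->I weight — the package's efficacy readout,
(weight after - weight before)/duration in nS/s.

## Worked example

`examples/02_electrical_ftsts.py` induces a seizure (200 pA for 3 s into
the 50 central excitatory neurons at t = 1 s) and applies the
inverted-standard protocol at t = 10 s for 5 s at its two optimal
train-offsets:

```
inverted-standard, offset -0.5 ms (increase): rate  +5.74 nS/s, total change  +28.7 nS
inverted-standard, offset -2.0 ms (decrease): rate  -5.73 nS/s, total change  -28.6 nS
```

A -0.5 ms offset forces presynaptic (excitatory) spikes just before
postsynaptic (inhibitory) ones and potentiates the pathway at ~+6 nS/s
from its 100 nS baseline; shifting the offset by only 1.5 ms reverses the
forced order and depresses it at the same rate.  The other examples cover
seizure induction (`01`), the four pulse polarities and charge balance
(`03`), the optogenetic Chronos/Chrimson variant (`04`) and seed-averaged
parameter sweeps (`05`).

A thin CLI wraps the same machinery for batch use:

```
ftsts simulate --config experiment.yaml --seed 1 --out out/
ftsts sweep    --config sweep.yaml --out out/
```

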