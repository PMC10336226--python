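"""Charge-balanced biphasic FTSTS pulse trains.

A forced-temporal-spike-time-stimulation (FTSTS) protocol delivers one
periodic biphasic square-pulse train to the excitatory population and one
to the inhibitory population.  A pulse pair consists of two contiguous
phases of width W and amplitude -A then +A (polarity +1) or +A then -A
(polarity -1), followed by T ms of zero current; the cycle period is
2W + T.  The positive phase forces spikes, the negative phase suppresses
them, so the pair of trains imposes a relative spike ordering between the
two populations which STDP converts into a directed change of the E->I
synaptic weight.

The train-offset time (delta_phi, ms) shifts the inhibitory train: it is
the start time of the inhibitory train minus that of the excitatory train,
so positive offsets delay the inhibitory train.  Waveforms are periodic in
the offset with period 2W + T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PulseTrainSpec",
    "ProtocolSpec",
    "StimRouting",
    "PROTOCOL_POLARITIES",
    "build_pulse_train",
    "route_stimulation",
]

#: protocol name -> (a_E, a_I)
PROTOCOL_POLARITIES: dict[str, tuple[int, int]] = {
    "standard": (+1, -1),
    "inverted-standard": (-1, +1),
    "mirrored": (+1, +1),
    "inverted-mirrored": (-1, -1),
}


@dataclass(frozen=True)
class PulseTrainSpec:
    """One population's biphasic pulse train.

    amplitude : A (nA); width : W (ms); inter_pulse_interval : T (ms);
    polarity : +1 (starts negative) or -1 (starts positive);
    onset/duration : stimulation window (ms).
    """

    amplitude: float = 2.0
    width: float = 1.0
    inter_pulse_interval: float = 10.0
    polarity: int = +1
    onset: float = 0.0
    duration: float = 5000.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be > 0")
        if self.inter_pulse_interval < 0:
            raise ValueError("inter-pulse interval must be >= 0")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def period(self) -> float:
        return 2.0 * self.width + self.inter_pulse_interval

    @property
    def frequency_hz(self) -> float:
        """Cycle rate implied by the pulse geometry (Hz)."""
        return 1000.0 / self.period


@dataclass(frozen=True)
class ProtocolSpec:
    """A full two-train FTSTS protocol.

    Defaults are the published protocol settings: 2 nA, 1 ms width, 10 ms
    inter-pulse interval (83 Hz cycle), zero train-offset, 5 s duration.
    ``name`` fixes the polarity pair; pass polarities explicitly via
    ``a_E``/``a_I`` by using name "custom".
    """

    name: str = "inverted-standard"
    a_E: int | None = None
    a_I: int | None = None
    amplitude: float = 2.0
    width: float = 1.0
    inter_pulse_interval: float = 10.0
    train_offset: float = 0.0
    onset: float = 10000.0
    duration: float = 5000.0
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.name != "custom":
            if self.name not in PROTOCOL_POLARITIES:
                raise ValueError(f"unknown protocol name {self.name!r}")
            pe, pi = PROTOCOL_POLARITIES[self.name]
            if self.a_E is None:
                object.__setattr__(self, "a_E", pe)
            if self.a_I is None:
                object.__setattr__(self, "a_I", pi)
            if (self.a_E, self.a_I) != (pe, pi):
                raise ValueError(
                    f"protocol {self.name!r} requires polarities {(pe, pi)}")
        elif self.a_E is None or self.a_I is None:
            raise ValueError("custom protocol requires explicit a_E and a_I")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")

    def train(self, population: str) -> PulseTrainSpec:
        """PulseTrainSpec for 'E' or 'I' (offset handled by the caller)."""
        polarity = self.a_E if population == "E" else self.a_I
        return PulseTrainSpec(
            amplitude=self.amplitude, width=self.width,
            inter_pulse_interval=self.inter_pulse_interval,
            polarity=polarity, onset=self.onset, duration=self.duration)


def build_pulse_train(spec: PulseTrainSpec, t_grid: np.ndarray,
                      offset: float = 0.0, dt: float | None = None
                      ) -> np.ndarray:
    """Sample the biphasic train on a uniform time grid (nA per sample).

    The train occupies [onset+offset, onset+offset+duration); within it,
    each period emits -a*A for W ms, +a*A for W ms, then T ms of zero.
    The grid step must divide the pulse width so waveforms are bit-exact.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if dt is None:
        if t_grid.size < 2:
            raise ValueError("need dt or a grid of >= 2 samples")
        dt = float(t_grid[1] - t_grid[0])
    ratio = spec.width / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"dt={dt} must divide the pulse width {spec.width} exactly")
    start = spec.onset + offset
    rel = t_grid - start
    # half-step tolerance keeps float-grid comparisons exact at boundaries
    eps = 1e-9 * max(1.0, abs(start))
    active = (rel >= -eps) & (rel < spec.duration - eps)
    phase = np.mod(rel, spec.period)
    wave = np.zeros_like(t_grid)
    a = float(spec.polarity) * spec.amplitude
    first = active & (phase < spec.width - eps)
    second = active & (phase >= spec.width - eps) & (phase < 2 * spec.width - eps)
    wave[first] = -a
    wave[second] = +a
    return wave


@dataclass(frozen=True)
class StimRouting:
    """Which neurons additionally receive the other population's train."""

    overlap_e: np.ndarray  # excitatory indices also receiving the I-train
    overlap_i: np.ndarray  # inhibitory indices also receiving the E-train


def route_stimulation(protocol: ProtocolSpec, n_e: int, n_i: int,
                      rng: np.random.Generator) -> StimRouting:
    """Assign trains to neurons, with partial E/I overlap.

    Every excitatory neuron receives the E-train and every inhibitory
    neuron the I-train; in addition, floor(overlap_fraction * N) randomly
    chosen neurons of each population (without replacement, independent
    draws per population) receive the other population's train summed in.
    """
    k_e = int(protocol.overlap_fraction * n_e)
    k_i = int(protocol.overlap_fraction * n_i)
    overlap_e = np.sort(rng.choice(n_e, size=k_e, replace=False))
    overlap_i = np.sort(rng.choice(n_i, size=k_i, replace=False))
    return StimRouting(overlap_e=overlap_e, overlap_i=overlap_i)
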