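"""Forward-Euler main loop composing neurons, connectivity, plasticity and
stimulation.

The network is two populations (N_E excitatory, N_I inhibitory) on a unit
line.  A seizure is initiated by a constant current pulse to a block of
excitatory neurons; stimulation protocols (electrical pulse trains and/or
optogenetic light schedules) are applied in configurable windows.  The
efficacy readout is the rate of change of the average E->I synaptic weight
over a stimulation window (nS/s).

Update order within a step (documented because it fixes the semantics of
"same-step" synaptic delivery): applied currents -> membrane Euler step ->
previous-step spike resets -> spike sampling -> spike-step resets ->
threshold relaxation -> conductance decay + delivery of this step's spikes
-> chloride -> STDP weight update (traces pre-increment) -> trace update.
Spikes emitted at step k therefore first influence membrane potentials at
step k+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .connectivity import WeightMatrices, build_connectivity
from .neuron import (PopulationState, apply_spike_reset, chloride_step,
                     conductance_step, membrane_step, sample_spikes,
                     threshold_step)
from .optogenetics import OptoAssignment, build_light_schedule, \
    schedule_conductance
from .params import ConnectivitySpec, ModelParams, STDPParams
from .plasticity import (PlasticState, average_ei_weight, stdp_trace_step,
                         stdp_weight_update)
from .protocols import ProtocolSpec, build_pulse_train, route_stimulation

__all__ = [
    "SeizureInput",
    "OptogeneticStim",
    "SimulationConfig",
    "SimulationResult",
    "run_simulation",
    "seizure_input",
    "efficacy_rate",
    "weight_change",
]


@dataclass(frozen=True)
class SeizureInput:
    """Seizure-initiating current: amplitude pA to a block of E neurons."""

    amplitude: float = 200.0
    start: float = 1000.0
    duration: float = 3000.0
    targets: tuple[int, int] | None = None  # [lo, hi) E indices; None = central 50

    def target_indices(self, n_e: int) -> np.ndarray:
        if self.targets is None:
            lo = n_e // 2 - 25
            hi = lo + 50
        else:
            lo, hi = self.targets
        if lo < 0 or hi > n_e or lo >= hi:
            raise ValueError("seizure target range invalid for population")
        return np.arange(lo, hi)


@dataclass(frozen=True)
class OptogeneticStim:
    """Optogenetic FTSTS window (see optogenetics.build_light_schedule).

    Flash geometry defaults (12 ms flashes every 62 ms; blue leading red by
    6 ms for the increase direction and by 2 ms for the decrease direction)
    are the calibrated operating point of the two-opsin protocol; see the
    methods note.  ``lead=None`` selects the per-direction default.
    """

    direction: str = "increase"
    onset: float = 10000.0
    duration: float = 10000.0
    flash_width: float = 12.0
    flash_interval: float = 50.0
    lead: float | None = None

    @property
    def resolved_lead(self) -> float:
        if self.lead is not None:
            return self.lead
        return 6.0 if self.direction == "increase" else 2.0


@dataclass
class SimulationConfig:
    """Everything needed for one reproducible run."""

    duration: float = 16000.0
    seed: int = 0
    model: ModelParams = field(default_factory=ModelParams)
    connectivity: ConnectivitySpec = field(default_factory=ConnectivitySpec)
    stdp: STDPParams = field(default_factory=STDPParams)
    seizure: SeizureInput | None = field(default_factory=SeizureInput)
    electrical: Sequence[ProtocolSpec] = ()
    optogenetic: Sequence[OptogeneticStim] = ()
    record_dt: float = 100.0
    snapshot_times: Sequence[float] = ()
    record_spikes: bool = True
    record_waveforms: bool = False

    def validate(self) -> None:
        dt = self.model.dt
        if self.duration <= 0 or self.duration < dt:
            raise ValueError("duration must cover at least one step")
        for stim in list(self.electrical) + list(self.optogenetic):
            if stim.onset < 0 or stim.onset + stim.duration > self.duration:
                raise ValueError(
                    f"stimulation window [{stim.onset}, "
                    f"{stim.onset + stim.duration}] outside the simulation")
        if self.seizure is not None:
            self.seizure.target_indices(self.connectivity.N_E)


@dataclass
class SimulationResult:
    """Raster, weight trace, snapshots and applied-waveform log."""

    config: SimulationConfig
    spike_ids_e: np.ndarray
    spike_times_e: np.ndarray
    spike_ids_i: np.ndarray
    spike_times_i: np.ndarray
    weight_times: np.ndarray          # ms
    avg_ei_weight: np.ndarray         # nS, aligned with weight_times
    snapshots: dict[float, np.ndarray]  # time -> effective E->I matrix
    waveforms: dict[str, np.ndarray] = field(default_factory=dict)

    def weight_at(self, t: float) -> float:
        """Average E->I weight at a sampled time (hard error if unsampled)."""
        idx = np.flatnonzero(np.isclose(self.weight_times, t, atol=1e-6))
        if idx.size == 0:
            raise ValueError(f"average weight was not sampled at t={t} ms")
        return float(self.avg_ei_weight[idx[0]])

    def save(self, outdir: str | Path) -> None:
        """Write raster and weight trace as CSV (CLI output format)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        e = np.column_stack([self.spike_ids_e, self.spike_times_e])
        i = np.column_stack([self.spike_ids_i, self.spike_times_i])
        np.savetxt(outdir / "raster_e.csv", e, delimiter=",",
                   header="neuron_id,time_ms", comments="", fmt="%d,%.3f")
        np.savetxt(outdir / "raster_i.csv", i, delimiter=",",
                   header="neuron_id,time_ms", comments="", fmt="%d,%.3f")
        np.savetxt(outdir / "avg_ei_weight.csv",
                   np.column_stack([self.weight_times, self.avg_ei_weight]),
                   delimiter=",", header="time_ms,avg_w_nS", comments="",
                   fmt="%.3f")


def seizure_input(seizure: SeizureInput | None, n_e: int, dt: float,
                  n_steps: int) -> tuple[np.ndarray, int, int, float]:
    """Per-step seizure current support: (target idx, k_start, k_stop, amp).

    The contribution at step k (time k*dt) is ``amp`` pA on the targets for
    k_start <= k < k_stop and zero otherwise / elsewhere.
    """
    if seizure is None:
        return np.empty(0, dtype=int), 0, 0, 0.0
    idx = seizure.target_indices(n_e)
    k0 = int(round(seizure.start / dt))
    k1 = int(round((seizure.start + seizure.duration) / dt))
    return idx, max(k0, 0), min(k1, n_steps), seizure.amplitude


def run_simulation(config: SimulationConfig,
                   weights: WeightMatrices | None = None) -> SimulationResult:
    """Run the full network simulation described by ``config``.

    Fully reproducible: all randomness (spike sampling, overlap routing)
    derives from ``config.seed``.  ``weights`` may be passed to reuse a
    prebuilt connectivity across runs.
    """
    config.validate()
    p = config.model
    stdp = config.stdp
    dt = p.dt
    n_steps = int(round(config.duration / dt))
    n_e, n_i = config.connectivity.N_E, config.connectivity.N_I

    ss = np.random.SeedSequence(config.seed)
    noise_seed, route_seed = ss.spawn(2)
    rng = np.random.default_rng(noise_seed)
    route_rng = np.random.default_rng(route_seed)

    if weights is None:
        weights = build_connectivity(config.connectivity)
    W_EE, W_EI = weights.W_EE, weights.W_EI
    W_II, W_IE = weights.W_II, weights.W_IE

    E = PopulationState.resting(n_e, p)
    I = PopulationState.resting(n_i, p)
    P = PlasticState.initial(n_e, n_i)

    t_grid = np.arange(n_steps) * dt
    sz_idx, sz_k0, sz_k1, sz_amp = seizure_input(
        config.seizure, n_e, dt, n_steps)

    # electrical stimulation: per protocol, waveforms (pA) + overlap routing
    elec = []
    for proto in config.electrical:
        wav_e = 1e3 * build_pulse_train(proto.train("E"), t_grid, 0.0, dt=dt)
        wav_i = 1e3 * build_pulse_train(proto.train("I"), t_grid,
                                        proto.train_offset, dt=dt)
        routing = route_stimulation(proto, n_e, n_i, route_rng)
        elec.append((wav_e, wav_i, routing.overlap_e, routing.overlap_i))

    # optogenetic stimulation: open-fraction waveforms per population
    opto = []
    for stim in config.optogenetic:
        asg: OptoAssignment = build_light_schedule(
            stim.direction, stim.onset, stim.duration,
            flash_width=stim.flash_width, flash_interval=stim.flash_interval,
            lead=stim.resolved_lead)
        F_e = schedule_conductance(asg.schedule_e, asg.opsin_e, t_grid)
        F_i = schedule_conductance(asg.schedule_i, asg.opsin_i, t_grid)
        opto.append((F_e, F_i, asg.opsin_e, asg.opsin_i))

    # weight-trace sample points: every record_dt, all window endpoints,
    # t=0 and the final step
    sample = np.zeros(n_steps + 1, dtype=bool)
    sample[0] = sample[-1] = True
    stride = max(int(round(config.record_dt / dt)), 1)
    sample[::stride] = True
    forced_times = []
    for stim in list(config.electrical) + list(config.optogenetic):
        forced_times += [stim.onset, stim.onset + stim.duration]
    for t in forced_times:
        k = int(round(t / dt))
        if 0 <= k <= n_steps:
            sample[k] = True
    snap_steps = {int(round(t / dt)) for t in config.snapshot_times}
    snap_steps |= {0, n_steps}

    weight_times: list[float] = []
    weight_vals: list[float] = []
    snapshots: dict[float, np.ndarray] = {}

    def record(k_done: int) -> None:
        if sample[k_done]:
            weight_times.append(k_done * dt)
            weight_vals.append(average_ei_weight(W_EI, P.Wp_EI))
        if k_done in snap_steps:
            snapshots[k_done * dt] = W_EI * P.Wp_EI

    record(0)

    spk_e_ids: list[np.ndarray] = []
    spk_e_t: list[np.ndarray] = []
    spk_i_ids: list[np.ndarray] = []
    spk_i_t: list[np.ndarray] = []

    I_app_e = np.zeros(n_e)
    I_app_i = np.zeros(n_i)
    prev_e = np.zeros(n_e, dtype=bool)
    prev_i = np.zeros(n_i, dtype=bool)
    zero_e = np.zeros(n_e)
    zero_i = np.zeros(n_i)

    for k in range(n_steps):
        t = k * dt
        I_app_e.fill(0.0)
        I_app_i.fill(0.0)
        if sz_k0 <= k < sz_k1:
            I_app_e[sz_idx] += sz_amp
        for wav_e, wav_i, ovl_e, ovl_i in elec:
            we, wi = wav_e[k], wav_i[k]
            if we != 0.0:
                I_app_e += we
                if ovl_i.size:
                    I_app_i[ovl_i] += we
            if wi != 0.0:
                I_app_i += wi
                if ovl_e.size:
                    I_app_e[ovl_e] += wi
        for F_e, F_i, ops_e, ops_i in opto:
            if F_e[k] > 0.0:
                I_app_e += -ops_e.g_ChR2 * F_e[k] * (E.V - ops_e.V_ChR2)
            if F_i[k] > 0.0:
                I_app_i += -ops_i.g_ChR2 * F_i[k] * (I.V - ops_i.V_ChR2)

        membrane_step(E, I_app_e, p, step=k)
        membrane_step(I, I_app_i, p, step=k)
        # the step after a spike: reset to (spike-step V) - 20 mV
        if prev_e.any():
            E.V[prev_e] = E.v_spike[prev_e] - 20.0
        if prev_i.any():
            I.V[prev_i] = I.v_spike[prev_i] - 20.0

        u = rng.random(n_e + n_i)  # fixed draw order: E block then I block
        spk_e = sample_spikes(E, p, rng, t, uniforms=u[:n_e])
        spk_i = sample_spikes(I, p, rng, t, uniforms=u[n_e:])
        apply_spike_reset(E, spk_e, p, t)
        apply_spike_reset(I, spk_i, p, t)
        threshold_step(E, p)
        threshold_step(I, p)

        e_idx = np.flatnonzero(spk_e)
        i_idx = np.flatnonzero(spk_i)
        if e_idx.size:
            in_e_from_e = (W_EE[e_idx] * P.Wp_EE[e_idx]).sum(axis=0)
            in_i_from_e = (W_EI[e_idx] * P.Wp_EI[e_idx]).sum(axis=0)
        else:
            in_e_from_e = zero_e
            in_i_from_e = zero_i
        if i_idx.size:
            in_e_from_i = W_IE[i_idx].sum(axis=0)
            in_i_from_i = W_II[i_idx].sum(axis=0)
        else:
            in_e_from_i = zero_e
            in_i_from_i = zero_i
        conductance_step(E, in_e_from_e, in_e_from_i, spk_e, p)
        conductance_step(I, in_i_from_e, in_i_from_i, spk_i, p)
        chloride_step(E, p, step=k)
        chloride_step(I, p, step=k)

        stdp_weight_update(P, spk_e, spk_i, stdp)
        stdp_trace_step(P, spk_e, spk_i, stdp, dt)

        if config.record_spikes:
            if e_idx.size:
                spk_e_ids.append(e_idx)
                spk_e_t.append(np.full(e_idx.size, t))
            if i_idx.size:
                spk_i_ids.append(i_idx)
                spk_i_t.append(np.full(i_idx.size, t))
        prev_e, prev_i = spk_e, spk_i
        record(k + 1)

    def cat(parts: list[np.ndarray], dtype) -> np.ndarray:
        return (np.concatenate(parts).astype(dtype) if parts
                else np.empty(0, dtype=dtype))

    waveforms: dict[str, np.ndarray] = {}
    if config.record_waveforms:
        for j, (wav_e, wav_i, _, _) in enumerate(elec):
            waveforms[f"electrical{j}_E_pA"] = wav_e
            waveforms[f"electrical{j}_I_pA"] = wav_i
        for j, (F_e, F_i, _, _) in enumerate(opto):
            waveforms[f"opto{j}_F_E"] = F_e
            waveforms[f"opto{j}_F_I"] = F_i

    return SimulationResult(
        config=config,
        spike_ids_e=cat(spk_e_ids, np.int32),
        spike_times_e=cat(spk_e_t, float),
        spike_ids_i=cat(spk_i_ids, np.int32),
        spike_times_i=cat(spk_i_t, float),
        weight_times=np.asarray(weight_times),
        avg_ei_weight=np.asarray(weight_vals),
        snapshots=snapshots,
        waveforms=waveforms,
    )


def weight_change(result: SimulationResult,
                  window: tuple[float, float]) -> float:
    """Change of the average E->I weight across a window (nS)."""
    t0, t1 = window
    return result.weight_at(t1) - result.weight_at(t0)


def efficacy_rate(result: SimulationResult,
                  window: tuple[float, float]) -> float:
    """Stimulation efficacy: weight change divided by window length (nS/s)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    return weight_change(result, window) / ((t1 - t0) / 1000.0)
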