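"""Reduced channelrhodopsin photocurrent model and light schedules.

The open-channel fraction F of an illuminated channelrhodopsin follows a
product of an activation rise and a partial-inactivation envelope,

    F(t) = A_act (1 - e^{-(t-t_on-d)/tau_act})
           (A_persist + A_inact1 e^{-(t-t_on-d)/tau_inact1}
                      + A_inact2 e^{-(t-t_on-d)/tau_inact2}),

with an intensity-dependent onset delay d and amplitudes; after light-off F
closes exponentially with tau_off.  The photocurrent entering the membrane
equation is I = -g_ChR2 * F * (V - V_ChR2).

Two opsins with separable action spectra (fast blue-driven Chronos, slow
red-driven Chrimson) let the two populations be driven independently; a
light schedule of brief flashes reproduces the FTSTS spike-ordering motif
optically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import CHRIMSON, CHRONOS, ChRParams

__all__ = [
    "LightPulse",
    "LightSchedule",
    "chr_activation_vars",
    "chr_conductance",
    "chr_current",
    "schedule_conductance",
    "build_light_schedule",
]


@dataclass(frozen=True)
class LightPulse:
    """One flash: [t_on, t_off) ms at dimensionless intensity W_light."""

    t_on: float
    t_off: float
    W_light: float

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ValueError("t_off must exceed t_on")


@dataclass
class LightSchedule:
    """Non-overlapping flashes on one optical channel."""

    channel: str  # "blue" or "red"
    pulses: list[LightPulse] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = sorted(self.pulses, key=lambda p: p.t_on)
        for a, b in zip(ts, ts[1:]):
            if b.t_on < a.t_off:
                raise ValueError("light pulses on one channel overlap")
        self.pulses = ts


def chr_activation_vars(W_light: float, params: ChRParams
                        ) -> tuple[float, float, float, float, float, float]:
    """Intensity-dependent quantities (d, tau_act, A_act, A_inact1,
    A_inact2, A_persist).

    d = d_A + d_B*W + d_C*W                 (onset delay, ms)
    tau_act = tau_act0 + c_act*e^{-k_act W} (activation time constant, ms)
    A_act = a0 + (a_min - 1)/(1 + (W_half/W)^2)
    A_inact1 = b0 + b1/(b2 + (W - W_inact)^2)
    A_inact2 = c_inact * e^{-k_inact W}
    A_persist = 1 - A_inact1 - A_inact2
    """
    if W_light <= 0:
        raise ValueError("W_light must be > 0")
    d = params.d_A + params.d_B * W_light + params.d_C * W_light
    tau_act = params.tau_act0 + params.c_act * np.exp(-params.k_act * W_light)
    A_act = params.a0 + (params.a_min - 1.0) / (
        1.0 + (params.W_half / W_light) ** 2)
    A_in1 = params.b0 + params.b1 / (
        params.b2 + (W_light - params.W_inact) ** 2)
    A_in2 = params.c_inact * np.exp(-params.k_inact * W_light)
    A_persist = 1.0 - A_in1 - A_in2
    return d, float(tau_act), float(A_act), float(A_in1), float(A_in2), float(A_persist)


def _pulse_waveform(tau_elapsed: np.ndarray, d: float, tau_act: float,
                    A_act: float, A_in1: float, A_in2: float,
                    A_persist: float, params: ChRParams) -> np.ndarray:
    """F during light-on as a function of elapsed time since t_on."""
    te = tau_elapsed - d
    te = np.where(te > 0, te, np.nan)
    F = A_act * (1.0 - np.exp(-te / tau_act)) * (
        A_persist + A_in1 * np.exp(-te / params.tau_inact1)
        + A_in2 * np.exp(-te / params.tau_inact2))
    return np.where(np.isnan(F), 0.0, F)


def chr_conductance(t: np.ndarray | float, pulse: LightPulse,
                    params: ChRParams) -> np.ndarray | float:
    """Open fraction F for a single isolated light pulse.

    Zero before the onset delay has elapsed; the activation/inactivation
    product during the pulse; exponential tau_off closure after t_off.
    """
    t = np.asarray(t, dtype=float)
    d, tau_act, A_act, A1, A2, Ap = chr_activation_vars(pulse.W_light, params)
    F_on = _pulse_waveform(t - pulse.t_on, d, tau_act, A_act, A1, A2, Ap,
                           params)
    F_off_level = _pulse_waveform(
        np.asarray(pulse.t_off - pulse.t_on), d, tau_act, A_act, A1, A2, Ap,
        params)
    F = np.where(t <= pulse.t_off, F_on,
                 F_off_level * np.exp(-(t - pulse.t_off) / params.tau_off))
    F = np.where(t < pulse.t_on, 0.0, F)
    return F if F.ndim else float(F)


def chr_current(V: np.ndarray | float, F: float,
                params: ChRParams) -> np.ndarray | float:
    """Photocurrent I = -g_ChR2 * F * (V - V_ChR2), in pA."""
    if F < 0:
        raise ValueError("open fraction F must be >= 0")
    return -params.g_ChR2 * F * (V - params.V_ChR2)


def schedule_conductance(schedule: LightSchedule, params: ChRParams,
                         t_grid: np.ndarray) -> np.ndarray:
    """Open fraction F(t) for a train of flashes on a uniform grid.

    Channels opened by earlier flashes keep closing with tau_off while new
    flashes open more, so the train waveform is the superposition of the
    residual off-decay and each pulse's activation transient.  For a single
    pulse this reduces exactly to ``chr_conductance``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    F = np.zeros_like(t_grid)
    residual = 0.0
    t_ref: float | None = None  # time the residual was measured (last off edge)
    lo = 0
    for pulse in schedule.pulses:
        i_on = int(np.searchsorted(t_grid, pulse.t_on, side="left"))
        i_off = int(np.searchsorted(t_grid, pulse.t_off, side="right"))
        if t_ref is not None and lo < i_off:
            F[lo:i_off] = residual * np.exp(
                -(t_grid[lo:i_off] - t_ref) / params.tau_off)
        d, tau_act, A_act, A1, A2, Ap = chr_activation_vars(
            pulse.W_light, params)
        if i_on < i_off:
            F[i_on:i_off] += _pulse_waveform(
                t_grid[i_on:i_off] - pulse.t_on, d, tau_act, A_act, A1, A2,
                Ap, params)
        prior = 0.0 if t_ref is None else residual * np.exp(
            -(pulse.t_off - t_ref) / params.tau_off)
        own = float(_pulse_waveform(np.asarray(pulse.t_off - pulse.t_on),
                                    d, tau_act, A_act, A1, A2, Ap, params))
        residual = prior + own
        t_ref = pulse.t_off
        lo = i_off
    if t_ref is not None and lo < t_grid.size:
        F[lo:] = residual * np.exp(-(t_grid[lo:] - t_ref) / params.tau_off)
    return F


@dataclass(frozen=True)
class OptoAssignment:
    """Schedules plus opsin parameter sets for the two populations."""

    schedule_e: LightSchedule
    schedule_i: LightSchedule
    opsin_e: ChRParams
    opsin_i: ChRParams


def build_light_schedule(direction: str, onset: float, duration: float,
                         flash_width: float = 1.0,
                         flash_interval: float = 10.0,
                         lead: float = 2.0,
                         chronos: ChRParams | None = None,
                         chrimson: ChRParams | None = None
                         ) -> OptoAssignment:
    """Construct the optogenetic FTSTS light schedules.

    direction="increase": Chronos (blue) in the excitatory population,
    Chrimson (red) in the inhibitory; blue flashes lead red by ``lead`` ms
    so excitatory (presynaptic) spikes precede inhibitory ones and the
    E->I weight potentiates.  direction="decrease": opsins swapped; blue
    flashes to the inhibitory population lead the red flashes to the
    excitatory population by ``lead`` ms, forcing post-before-pre.

    Flashes are ``flash_width`` ms long and repeat every
    flash_width + flash_interval ms throughout [onset, onset+duration).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    chronos = chronos if chronos is not None else CHRONOS()
    chrimson = chrimson if chrimson is not None else CHRIMSON()
    period = flash_width + flash_interval
    n = max(int(np.floor((duration - flash_width) / period)) + 1, 0) \
        if duration >= flash_width else 0

    def flashes(t0: float, w_light: float) -> list[LightPulse]:
        return [LightPulse(t0 + k * period, t0 + k * period + flash_width,
                           w_light)
                for k in range(n)
                if t0 + k * period + flash_width <= onset + duration]

    if direction == "increase":
        opsin_e, opsin_i = chronos, chrimson
        blue_to, red_to = "E", "I"
    else:
        opsin_e, opsin_i = chrimson, chronos
        blue_to, red_to = "I", "E"
    blue_t0, red_t0 = onset, onset + lead
    sched = {
        blue_to: LightSchedule("blue", flashes(blue_t0,
                                               (chronos.W_light))),
        red_to: LightSchedule("red", flashes(red_t0, (chrimson.W_light))),
    }
    return OptoAssignment(schedule_e=sched["E"], schedule_i=sched["I"],
                          opsin_e=opsin_e, opsin_i=opsin_i)
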