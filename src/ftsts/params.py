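"""Model parameter containers.

All quantities use the internal unit system {mV, nS, pF, pA, ms, mM}: with
these units nS*mV = pA and pA/pF = mV/ms, so the membrane equation needs no
conversion factors.  Firing rates are stored in Hz and converted to ms^-1
where they enter per-step arithmetic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ModelParams",
    "STDPParams",
    "ConnectivitySpec",
    "ChRParams",
    "CHRONOS",
    "CHRIMSON",
    "load_params",
    "dump_params",
]


@dataclass
class ModelParams:
    """Biophysical constants of one conductance-based integrate-and-fire neuron.

    Defaults reproduce the neocortical seizure network: stochastic
    (inhomogeneous-Poisson) spiking with an adaptive threshold, exponential
    synaptic and sAHP conductances, and chloride-dependent GABA reversal.

    Attributes
    ----------
    C : membrane capacitance (pF).
    g_L : leak conductance (nS).
    E_L, E_E, E_K : leak / glutamatergic / potassium reversal potentials (mV).
    f0 : baseline firing rate at threshold (Hz).
    beta : softness of the spike threshold (mV).
    tau_ref : absolute refractory period (ms).
    tau_syn : synaptic conductance decay time constant (ms).
    tau_phi : threshold relaxation time constant (ms).
    phi0 : baseline firing threshold (mV).
    delta_phi : post-spike threshold increment (mV, signed).  The default
        (+4 mV) is calibrated so the resting network stays near the
        spontaneous rate while suprathreshold drive still recruits
        seizure-like activity; see the methods note for the rationale.
    delta_K : sAHP increment numerator (nS); each spike adds delta_K/tau_K.
    f_max : dimensionless per-ms scaling of the synaptic and sAHP
        conductances (0.2 = inverse of the 5 ms refractory period in ms^-1).
    V_d : volume of distribution for internal chloride (pL).
    F : Faraday constant (C/mol).
    Cl_in_eq, Cl_out : equilibrium internal / fixed external chloride (mM).
    tau_Cl, tau_K : chloride and sAHP time constants (ms).
    dt : integration step (ms).
    nernst_natural_log : if False use log10 in the Nernst relation
        (physiological default is the natural log: 26.7 mV ~ RT/F).
    cl_flux_fmax : include the f_max conductance scaling in the chloride
        flux term so the flux equals the GABAergic current of the membrane
        equation.
    reset_from_pre_average : the next-step reset after a spike subtracts
        20 mV from the membrane potential as it stood BEFORE the spike-step
        averaging with 40 mV (True, default) or after it (False).  The
        pre-averaging convention leaves a spiking neuron hyperpolarized and
        is required for a quiescent resting network with a mild threshold
        increment; see the methods note.
    """

    C: float = 100.0
    g_L: float = 4.0
    E_L: float = -57.0
    E_E: float = 0.0
    E_K: float = -90.0
    f0: float = 2.0
    beta: float = 1.5
    tau_ref: float = 5.0
    tau_syn: float = 15.0
    tau_phi: float = 100.0
    phi0: float = -55.0
    delta_phi: float = 4.0
    delta_K: float = 40.0
    f_max: float = 0.2
    V_d: float = 0.2357
    F: float = 96500.0
    Cl_in_eq: float = 6.0
    Cl_out: float = 110.0
    tau_Cl: float = 5000.0
    tau_K: float = 5000.0
    dt: float = 0.5
    nernst_natural_log: bool = True
    cl_flux_fmax: bool = True
    reset_from_pre_average: bool = True

    def __post_init__(self) -> None:
        for name in ("tau_ref", "tau_syn", "tau_phi", "tau_Cl", "tau_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.C <= 0 or self.dt <= 0:
            raise ValueError("C and dt must be > 0")
        if self.Cl_out <= 0 or self.Cl_in_eq <= 0:
            raise ValueError("chloride concentrations must be > 0")

    @property
    def f0_per_ms(self) -> float:
        return self.f0 * 1e-3


@dataclass
class STDPParams:
    """Trace-based Hebbian STDP parameters.

    eta : learning rate (dimensionless fraction per pairing).
    tau_stdp : eligibility-trace time constant (ms).
    A0 : trace increment per spike (dimensionless; not printed in the source
        parameter table, default 1).
    """

    eta: float = 1e-3
    tau_stdp: float = 15.0
    A0: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.tau_stdp <= 0 or self.A0 <= 0:
            raise ValueError("eta, tau_stdp and A0 must be > 0")


@dataclass
class ConnectivitySpec:
    """Geometry and scaling of the four static weight matrices.

    Neurons sit on a unit line at normalized positions k/N; Gaussian kernels
    with sd sigma_E (excitatory projections) or sigma_I (inhibitory) are
    row-normalized and scaled so each presynaptic neuron distributes exactly
    W0 across its targets.  Inhibitory projections additionally carry a weak
    uniform component W_UI split evenly over targets.
    """

    N_E: int = 500
    N_I: int = 500
    sigma_E: float = 0.02
    sigma_I: float = 0.03
    W0_EE: float = 104.0
    W0_EI: float = 100.0
    W0_II: float = 250.0
    W0_IE: float = 250.0
    W_UI: float = 50.0

    def __post_init__(self) -> None:
        if self.N_E <= 0 or self.N_I <= 0:
            raise ValueError("population sizes must be > 0")
        if self.sigma_E <= 0 or self.sigma_I <= 0:
            raise ValueError("kernel widths must be > 0")
        for name in ("W0_EE", "W0_EI", "W0_II", "W0_IE", "W_UI"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ChRParams:
    """Reduced channelrhodopsin photocurrent model constants.

    The conductance waveform F(t) of an illuminated channel rises with
    activation time constant tau_act and partially inactivates toward a
    persistent plateau; after light-off it closes exponentially with
    tau_off.  Intensity-dependent amplitudes follow rational/exponential
    fits (see optogenetics module).  gamma is carried in the parameter set
    for completeness but enters no default equation.
    """

    name: str = "chronos"
    W_inact: float = 0.11
    tau_inact1: float = 9.06
    tau_inact2: float = 59.6
    d_A: float = 0.27
    d_B: float = -0.05
    d_C: float = -0.0126
    tau_act0: float = 0.74
    c_act: float = 12.0
    k_act: float = 25.0
    a0: float = 1.0
    a_min: float = 0.4
    W_half: float = 0.38
    b0: float = 0.16
    b1: float = 0.013
    b2: float = 0.027
    c_inact: float = 0.29
    k_inact: float = 2.4
    V_ChR2: float = 0.0
    g_ChR2: float = 294.0
    tau_off: float = 3.6
    gamma: float = 1.0 / 6.0
    W_light: float = 0.0308

    def __post_init__(self) -> None:
        for name in ("tau_inact1", "tau_inact2", "tau_act0", "tau_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.g_ChR2 < 0:
            raise ValueError("g_ChR2 must be >= 0")


def CHRONOS() -> ChRParams:
    """Fast blue-light (470 nm) channelrhodopsin preset."""
    return ChRParams(name="chronos", tau_off=3.6, W_light=0.0308)


def CHRIMSON() -> ChRParams:
    """Slow red-light (625 nm) channelrhodopsin preset."""
    return ChRParams(name="chrimson", tau_off=15.8, W_light=0.0023)


_SECTIONS = {
    "model": ModelParams,
    "stdp": STDPParams,
    "connectivity": ConnectivitySpec,
    "chr": ChRParams,
}


def load_params(path: str | Path) -> dict[str, Any]:
    """Load parameter sections from a YAML file.

    Recognized top-level keys: ``model``, ``stdp``, ``connectivity``,
    ``chr``; each maps field names (as in the dataclasses above, which
    mirror the published parameter tables) to values.  Unknown fields are
    rejected to catch typos.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = {}
    for key, cls in _SECTIONS.items():
        if key in raw:
            fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(raw[key]) - fields
            if unknown:
                raise KeyError(f"unknown {key} parameters: {sorted(unknown)}")
            out[key] = cls(**raw[key])
    return out


def dump_params(sections: dict[str, Any], path: str | Path) -> None:
    """Write parameter dataclasses back to YAML (inverse of load_params)."""
    payload = {
        key: dataclasses.asdict(val) for key, val in sections.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
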