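"""Per-step dynamics of one neuron population.

Each operation advances one piece of the state by a single forward-Euler
step of length ``params.dt``.  The population is vectorized: every state
variable is a 1-D array over neurons.  Spiking is stochastic: the
instantaneous rate f = f0*exp((V - phi)/beta) is converted to a per-step
spike probability p = 1 - exp(-f*dt) (exact per-step thinning of an
inhomogeneous Poisson process), with an absolute refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "PopulationState",
    "membrane_step",
    "sample_spikes",
    "apply_spike_reset",
    "threshold_step",
    "conductance_step",
    "chloride_step",
    "nernst",
]


@dataclass
class PopulationState:
    """State arrays of one population of stochastic integrate-and-fire neurons.

    V : membrane potential (mV)
    phi : adaptive firing threshold (mV)
    g_E, g_I, g_K : glutamatergic / GABAergic / sAHP conductances (nS)
    Cl_in : internal chloride concentration (mM)
    E_Cl : GABA reversal potential from the Nernst relation (mV)
    t_last_spike : most recent spike time (ms; -inf if never)
    v_spike : membrane potential recorded at the most recent spike step
        (used for the next-step -20 mV reset)
    """

    V: np.ndarray
    phi: np.ndarray
    g_E: np.ndarray
    g_I: np.ndarray
    g_K: np.ndarray
    Cl_in: np.ndarray
    E_Cl: np.ndarray
    t_last_spike: np.ndarray
    v_spike: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.V.shape[0]
        if self.v_spike is None:
            self.v_spike = np.zeros(n)
        arrays = (self.phi, self.g_E, self.g_I, self.g_K, self.Cl_in,
                  self.E_Cl, self.t_last_spike, self.v_spike)
        if any(a.shape != (n,) for a in arrays):
            raise ValueError("all state arrays must share one length")

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def save(self, path) -> None:
        """Serialize the state arrays to an .npz store with named datasets."""
        np.savez(path, V=self.V, phi=self.phi, g_E=self.g_E, g_I=self.g_I,
                 g_K=self.g_K, Cl_in=self.Cl_in, E_Cl=self.E_Cl,
                 t_last_spike=self.t_last_spike, v_spike=self.v_spike)

    @classmethod
    def load(cls, path) -> "PopulationState":
        with np.load(path) as data:
            return cls(**{k: data[k] for k in data.files})

    @classmethod
    def resting(cls, n: int, params: ModelParams) -> "PopulationState":
        """Population at the leak/equilibrium fixed point."""
        cl = np.full(n, params.Cl_in_eq)
        return cls(
            V=np.full(n, params.E_L),
            phi=np.full(n, params.phi0),
            g_E=np.zeros(n),
            g_I=np.zeros(n),
            g_K=np.zeros(n),
            Cl_in=cl,
            E_Cl=nernst(cl, params),
            t_last_spike=np.full(n, -np.inf),
        )


def nernst(Cl_in: np.ndarray, params: ModelParams) -> np.ndarray:
    """GABA reversal potential E_Cl = -26.7 mV * ln([Cl_out]/[Cl_in])."""
    ratio = params.Cl_out / Cl_in
    log = np.log(ratio) if params.nernst_natural_log else np.log10(ratio)
    return -26.7 * log


def membrane_step(state: PopulationState, I_app: np.ndarray,
                  params: ModelParams, step: int | None = None) -> np.ndarray:
    """Advance V one Euler step of the conductance-based membrane equation.

    dV/dt = [g_L(E_L-V) + f_max(g_E(E_E-V) + g_I(E_Cl-V) + g_K(E_K-V))
             + I_app] / C

    I_app is the total externally applied current per neuron (pA), including
    any seizure-inducing, electrical-stimulation or photocurrent terms.
    """
    V = state.V
    if I_app.shape != V.shape:
        raise ValueError(f"I_app shape {I_app.shape} != state shape {V.shape}")
    dV = (params.g_L * (params.E_L - V)
          + params.f_max * (state.g_E * (params.E_E - V)
                            + state.g_I * (state.E_Cl - V)
                            + state.g_K * (params.E_K - V))
          + I_app) * (params.dt / params.C)
    V += dV
    # cheap aggregate check first; inf/nan both poison the sum
    if not np.isfinite(V.sum()) and not np.all(np.isfinite(V)):
        where = "" if step is None else f" at step {step}"
        raise FloatingPointError(f"non-finite membrane potential{where}")
    return V


def sample_spikes(state: PopulationState, params: ModelParams,
                  rng: np.random.Generator, t: float,
                  uniforms: np.ndarray | None = None) -> np.ndarray:
    """Draw this step's spikes from the voltage-dependent Poisson rate.

    Returns a boolean mask.  Neurons within tau_ref of their last spike
    never fire.  ``uniforms`` lets the caller supply the per-neuron uniform
    draws (to fix the draw order across populations); otherwise one draw
    per neuron is taken from ``rng``.
    """
    expo = np.minimum((state.V - state.phi) / params.beta, 50.0)
    f = params.f0_per_ms * np.exp(expo)          # ms^-1
    p = -np.expm1(-f * params.dt)                # 1 - exp(-f dt), <= 1
    if uniforms is None:
        uniforms = rng.random(state.n)
    mask = uniforms < p
    mask &= (t - state.t_last_spike) >= params.tau_ref
    return mask


def apply_spike_reset(state: PopulationState, spike_mask: np.ndarray,
                      params: ModelParams, t: float) -> None:
    """Apply the spike-step half of the reset rule.

    At the spike step the membrane potential is set to the average of 40 mV
    and its current value; the threshold jumps by delta_phi; the spike time
    is recorded.  The following step's reset to V - 20 mV (from the pre- or
    post-averaging potential, per ``params.reset_from_pre_average``) is
    applied by the caller via ``state.v_spike`` (see engine).
    """
    if not spike_mask.any():
        return
    V_pre = state.V[spike_mask]
    Vs = 0.5 * (40.0 + V_pre)
    state.V[spike_mask] = Vs
    base = V_pre if params.reset_from_pre_average else Vs
    state.v_spike[spike_mask] = base  # engine applies base - 20 next step
    state.phi[spike_mask] += params.delta_phi
    state.t_last_spike[spike_mask] = t


def threshold_step(state: PopulationState, params: ModelParams) -> np.ndarray:
    """Relax the firing threshold toward phi0: tau_phi dphi/dt = phi0 - phi."""
    state.phi += (params.phi0 - state.phi) * (params.dt / params.tau_phi)
    return state.phi


def conductance_step(state: PopulationState,
                     exc_input: np.ndarray | float,
                     inh_input: np.ndarray | float,
                     own_spikes: np.ndarray,
                     params: ModelParams) -> None:
    """Decay g_E, g_I (tau_syn) and g_K (tau_K); add presynaptic weight sums.

    ``exc_input``/``inh_input`` are the per-neuron sums of effective
    presynaptic weights (nS) of this step's excitatory/inhibitory spikes.
    Each neuron that itself spiked gains delta_K/tau_K of sAHP conductance.
    """
    for inp in (exc_input, inh_input):
        lo = inp.min() if isinstance(inp, np.ndarray) else inp
        if lo < 0:
            raise ValueError("presynaptic weight sums must be non-negative")
    dt = params.dt
    state.g_E *= 1.0 - dt / params.tau_syn
    state.g_I *= 1.0 - dt / params.tau_syn
    state.g_K *= 1.0 - dt / params.tau_K
    state.g_E += exc_input
    state.g_I += inh_input
    if own_spikes.any():
        state.g_K[own_spikes] += params.delta_K / params.tau_K


def chloride_step(state: PopulationState, params: ModelParams,
                  step: int | None = None) -> None:
    """Advance internal chloride and re-derive the GABA reversal potential.

    The chloride load equals the GABAergic membrane current: while V is
    above E_Cl an open GABA-A channel carries chloride inward, so

        d[Cl_in]/dt = g_I*f_max*(V - E_Cl)/(V_d*F)
                      + ([Cl_in,eq] - [Cl_in])/tau_Cl

    followed by E_Cl = -26.7 ln([Cl_out]/[Cl_in]).  With {pA, pL, C/mol}
    the flux term is in mM/ms with no conversion factor.
    """
    scale = params.f_max if params.cl_flux_fmax else 1.0
    flux = state.g_I * scale * (state.V - state.E_Cl) / (params.V_d * params.F)
    relax = (params.Cl_in_eq - state.Cl_in) / params.tau_Cl
    state.Cl_in += params.dt * (flux + relax)
    if np.any(state.Cl_in <= 0):
        where = "" if step is None else f" at step {step}"
        raise FloatingPointError(
            f"internal chloride became non-positive{where}; check units")
    state.E_Cl[:] = nernst(state.Cl_in, params)
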