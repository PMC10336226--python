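"""Trace-based Hebbian STDP on excitatory projections.

Only E->E and E->I synapses are plastic.  Each synapse carries a
multiplicative plastic fraction Wp (initialized to 1); the effective weight
delivered on a spike is W_base * Wp.  Every neuron keeps an eligibility
trace that decays with tau_stdp and jumps by A0 at its own spikes
(all-to-all pairing):

* presynaptic spike at j:  Wp[j, :] -= eta * A_post   (depression)
* postsynaptic spike at i: Wp[:, i] += eta * A_pre    (potentiation)

so a pre-before-post pairing at lag dt changes Wp by +eta*A0*exp(-dt/tau)
and the reverse order by -eta*A0*exp(-dt/tau).  Wp is clamped at zero
below and unbounded above.

Weight updates are applied with the traces as they stood BEFORE the current
step's spikes, so exactly coincident pre/post spikes produce no net change;
traces are incremented afterwards (``stdp_trace_step``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import STDPParams

__all__ = [
    "PlasticState",
    "stdp_trace_step",
    "stdp_weight_update",
    "average_ei_weight",
]


@dataclass
class PlasticState:
    """Plastic fractions and eligibility traces.

    A_pre : trace of each presynaptic excitatory neuron
    A_post_e / A_post_i : traces of postsynaptic excitatory / inhibitory
        neurons (A_post_e doubles as the E-population presynaptic trace's
        postsynaptic counterpart on E->E synapses)
    Wp_EE, Wp_EI : multiplicative plastic fractions, [pre, post]
    """

    A_pre: np.ndarray
    A_post_e: np.ndarray
    A_post_i: np.ndarray
    Wp_EE: np.ndarray
    Wp_EI: np.ndarray

    @classmethod
    def initial(cls, n_e: int, n_i: int) -> "PlasticState":
        return cls(
            A_pre=np.zeros(n_e),
            A_post_e=np.zeros(n_e),
            A_post_i=np.zeros(n_i),
            Wp_EE=np.ones((n_e, n_e)),
            Wp_EI=np.ones((n_e, n_i)),
        )


def stdp_trace_step(state: PlasticState, e_spikes: np.ndarray,
                    i_spikes: np.ndarray, params: STDPParams,
                    dt: float) -> None:
    """Euler-decay all traces, then add A0 at this step's own spikes."""
    decay = 1.0 - dt / params.tau_stdp
    state.A_pre *= decay
    state.A_post_e *= decay
    state.A_post_i *= decay
    if e_spikes.any():
        state.A_pre[e_spikes] += params.A0
        state.A_post_e[e_spikes] += params.A0
    if i_spikes.any():
        state.A_post_i[i_spikes] += params.A0


def stdp_weight_update(state: PlasticState, e_spikes: np.ndarray,
                       i_spikes: np.ndarray, params: STDPParams) -> None:
    """Apply the pair rule for this step's spikes (traces pre-increment).

    ``e_spikes`` plays both roles: presynaptic for depression of the rows
    of Wp_EE and Wp_EI, and postsynaptic for potentiation of Wp_EE columns.
    ``i_spikes`` potentiates Wp_EI columns.
    """
    eta = params.eta
    if e_spikes.any():
        idx = np.flatnonzero(e_spikes)
        # depression on every outgoing synapse of a spiking presynaptic cell
        state.Wp_EE[idx] = np.maximum(
            state.Wp_EE[idx] - eta * state.A_post_e[None, :], 0.0)
        state.Wp_EI[idx] = np.maximum(
            state.Wp_EI[idx] - eta * state.A_post_i[None, :], 0.0)
        # potentiation on every incoming E->E synapse of a spiking E cell
        state.Wp_EE[:, idx] += eta * state.A_pre[:, None]
    if i_spikes.any():
        idx = np.flatnonzero(i_spikes)
        state.Wp_EI[:, idx] += eta * state.A_pre[:, None]


def average_ei_weight(W_EI: np.ndarray, Wp_EI: np.ndarray) -> float:
    """Mean total effective E->I input per inhibitory neuron (nS).

    With row-sum-conserving connectivity and Wp = 1 this equals the E->I
    budget W0_EI, so the baseline reads 100 nS and stimulation-induced
    excursions are directly comparable across runs.
    """
    if W_EI.shape != Wp_EI.shape:
        raise ValueError(
            f"shape mismatch: {W_EI.shape} vs {Wp_EI.shape}")
    return float((W_EI * Wp_EI).sum(axis=0).mean())
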