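"""Distance-dependent static synaptic weight matrices.

Neurons of each population are placed on a unit-length open line at
normalized positions k/N.  Each presynaptic neuron projects with a Gaussian
kernel of its population's width; rows are normalized to sum to one and
scaled by the population-pair budget W0, so every presynaptic neuron
distributes exactly W0 (nS) across its targets regardless of edge
truncation.  Inhibitory projections additionally carry a weak uniform
synapse W_UI/N_target on every entry.

Matrices are indexed [presynaptic, postsynaptic] and are fully
deterministic functions of the spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .params import ConnectivitySpec

__all__ = ["WeightMatrices", "build_connectivity", "gaussian_kernel"]


@dataclass
class WeightMatrices:
    """The four static base weight matrices (nS), [pre, post]."""

    W_EE: np.ndarray
    W_EI: np.ndarray
    W_II: np.ndarray
    W_IE: np.ndarray

    def save_csv(self, directory: str | Path) -> None:
        """Write each matrix as a plain CSV (small test networks only)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("W_EE", "W_EI", "W_II", "W_IE"):
            np.savetxt(directory / f"{name}.csv", getattr(self, name),
                       delimiter=",")

    @classmethod
    def load_csv(cls, directory: str | Path) -> "WeightMatrices":
        directory = Path(directory)
        return cls(**{
            name: np.atleast_2d(
                np.loadtxt(directory / f"{name}.csv", delimiter=","))
            for name in ("W_EE", "W_EI", "W_II", "W_IE")
        })


def gaussian_kernel(n_pre: int, n_post: int, sigma: float) -> np.ndarray:
    """Unnormalized Gaussian kernel over normalized inter-neuron distance.

    K[i, j] = normpdf(|i/n_pre - j/n_post|; 0, sigma); distances live on the
    unit line, matching kernel widths quoted in normalized position units.
    """
    x_pre = np.arange(n_pre) / n_pre
    x_post = np.arange(n_post) / n_post
    d = np.abs(x_pre[:, None] - x_post[None, :])
    return norm.pdf(d, loc=0.0, scale=sigma)


def _row_scaled(kernel: np.ndarray, w0: float) -> np.ndarray:
    sums = kernel.sum(axis=1, keepdims=True)
    if np.any(sums <= 0) or not np.all(np.isfinite(sums)):
        raise ValueError("kernel row underflowed to zero; sigma too small")
    return w0 * kernel / sums


def build_connectivity(spec: ConnectivitySpec) -> WeightMatrices:
    """Construct the four weight matrices from a connectivity spec.

    Excitatory projections (E->E, E->I) use sigma_E; inhibitory projections
    (I->I, I->E) use sigma_I and gain the uniform W_UI/N_target term after
    row normalization.
    """
    K_E_to_E = gaussian_kernel(spec.N_E, spec.N_E, spec.sigma_E)
    K_E_to_I = gaussian_kernel(spec.N_E, spec.N_I, spec.sigma_E)
    K_I_to_I = gaussian_kernel(spec.N_I, spec.N_I, spec.sigma_I)
    K_I_to_E = gaussian_kernel(spec.N_I, spec.N_E, spec.sigma_I)
    return WeightMatrices(
        W_EE=_row_scaled(K_E_to_E, spec.W0_EE),
        W_EI=_row_scaled(K_E_to_I, spec.W0_EI),
        W_II=_row_scaled(K_I_to_I, spec.W0_II) + spec.W_UI / spec.N_I,
        W_IE=_row_scaled(K_I_to_E, spec.W0_IE) + spec.W_UI / spec.N_E,
    )
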