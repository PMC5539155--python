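"""Mass-action random walk and its invariant measure.

Each sample turns the shared topology into a weighted graph by mass action:
the walker at gene *i* steps to neighbor *j* with probability proportional
to *j*'s expression,

    p_ij = x_j / sum_{k in N(i)} x_k,        j in N(i),

so interactions between highly expressed genes carry more probability flow.
For this particular chain the stationary distribution has a closed form,

    pi_i = x_i * sum_{j in N(i)} x_j / Z,

with Z the normalization (partition function): a gene is important when it
is highly expressed *and* its interaction partners are. The closed form is
the production path; a power-iteration eigensolver is kept as an
independent numerical oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import ExpressionProfile, GeneNetwork

__all__ = [
    "InvariantMeasure",
    "build_transition_matrix",
    "stationary_closed_form",
    "stationary_eigensolve",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class InvariantMeasure:
    """Stationary probability vector over network nodes.

    ``z`` is the normalization constant of the closed form, retained for
    audit; it is NaN for measures not produced by the closed form.
    """

    sample_id: str
    pi: np.ndarray = field(repr=False)
    z: float = float("nan")

    def __post_init__(self):
        p = np.asarray(self.pi, dtype=np.float64).ravel()
        object.__setattr__(self, "pi", p)
        if np.any(p < 0):
            raise ValueError(f"measure {self.sample_id!r}: negative entries")
        s = p.sum()
        if not np.isclose(s, 1.0, rtol=0, atol=1e-9):
            raise ValueError(f"measure {self.sample_id!r}: sums to {s!r}, not 1")


def build_transition_matrix(
    network: GeneNetwork, profile: ExpressionProfile
) -> sp.csr_matrix:
    """Row-stochastic mass-action transition matrix P.

    Sparsity pattern equals the adjacency; p_ij = x_j / sum_{k in N(i)} x_k.
    """
    profile.validate_against(network)
    x = profile.values
    adj = network.adjacency()
    neighbor_mass = adj @ x  # sum of neighbor expression per node; >0 since deg>=1, x>0
    # P = diag(1/neighbor_mass) @ A @ diag(x)
    p = adj.multiply(x[np.newaxis, :]).multiply(1.0 / neighbor_mass[:, np.newaxis])
    p = sp.csr_matrix(p)
    row_err = np.abs(np.asarray(p.sum(axis=1)).ravel() - 1.0).max()
    if row_err > 1e-10:
        raise AssertionError(f"transition matrix rows deviate from 1 by {row_err:g}")
    return p


def stationary_closed_form(
    network: GeneNetwork, profile: ExpressionProfile
) -> InvariantMeasure:
    """Closed-form stationary measure pi_i = x_i (A x)_i / Z."""
    network.require_connected("the stationary measure")
    profile.validate_against(network)
    x = profile.values
    unnormalized = x * (network.adjacency() @ x)
    z = float(unnormalized.sum())
    return InvariantMeasure(sample_id=profile.sample_id, pi=unnormalized / z, z=z)


def stationary_eigensolve(
    p: sp.spmatrix,
    sample_id: str = "",
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> InvariantMeasure:
    """Stationary vector of a row-stochastic P by power iteration.

    Iterates the lazy chain (P + I)/2, which shares the stationary vector
    of P but is aperiodic — plain iteration of P cycles forever on
    bipartite topologies (for instance trees). Serves as the independent
    oracle for :func:`stationary_closed_form`.
    """
    p = sp.csr_matrix(p)
    n = p.shape[0]
    pt = p.T.tocsr()
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = 0.5 * (pt @ pi + pi)
        nxt /= nxt.sum()
        if np.abs(nxt - pi).max() <= tol:
            pi = nxt
            break
        pi = nxt
    else:
        residual = np.abs(pt @ pi - pi).max()
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )
    return InvariantMeasure(sample_id=sample_id, pi=pi / pi.sum())


def stationarity_residual(pi: np.ndarray, p: sp.spmatrix) -> float:
    """max-norm of pi P - pi; the defining identity of an invariant measure."""
    pi = np.asarray(pi, dtype=np.float64).ravel()
    return float(np.abs(pi @ sp.csr_matrix(p) - pi).max())
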