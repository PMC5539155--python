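"""Wasserstein-1 (Earth Mover's) distance between measures on a graph.

Three mutually checking linear-programming formulations of the same
distance, with ground metric the hop count (each edge costs 1):

* ``w1_coupling`` — the primal optimal-transport LP over an n x n coupling
  mu with marginals rho0 and rho1 and cost sum c_ij mu_ij. Exact but has
  n^2 variables; used as the small-instance oracle.
* ``w1_flux`` — the equivalent min-cost-flow LP over signed edge fluxes u
  with divergence constraint rho0 - rho1 - D u = 0, D the oriented
  incidence matrix. Only m variables (2m after splitting |u|), so this is
  the production solver on sparse graphs.
* ``w1_dual`` — the Kantorovich dual: maximize f . (rho0 - rho1) over node
  potentials f that are 1-Lipschitz edge-wise (|f_i - f_j| <= 1 on every
  edge, the graph form of a Lipschitz bound under the hop metric). Second
  oracle; equality of all three is strong duality.

All three use ``scipy.optimize.linprog`` (HiGHS by default) on sparse
constraint matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.sparse.csgraph import shortest_path

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GroundMetric",
    "TransportPlan",
    "FlowVector",
    "PotentialVector",
    "shortest_path_costs",
    "incidence_matrix",
    "w1_flux",
    "w1_coupling",
    "w1_dual",
]

#: inputs must carry equal mass to within this before renormalization
MASS_TOL = 1e-9
#: maximum acceptable constraint residual of a solver's answer
FEASIBILITY_TOL = 1e-7
#: node-count guard for the dense n^2-variable coupling LP
COUPLING_MAX_NODES = 200


@dataclass(frozen=True)
class GroundMetric:
    """All-pairs hop-count cost table c (symmetric, zero diagonal)."""

    c: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class TransportPlan:
    """Optimal coupling mu: mu[i, j] is mass moved from node i to node j."""

    mu: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class FlowVector:
    """Signed optimal flux per edge, in the network's fixed edge order."""

    u: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class PotentialVector:
    """Kantorovich potential per node (edge-wise 1-Lipschitz)."""

    f: np.ndarray = field(repr=False)


def shortest_path_costs(network: GeneNetwork) -> GroundMetric:
    """Unweighted shortest-path hop counts between all node pairs."""
    c = shortest_path(network.adjacency(), method="D", unweighted=True, directed=False)
    if not np.all(np.isfinite(c)):
        raise ValueError(
            "network is disconnected: some node pairs are unreachable; "
            "take the largest connected component first"
        )
    return GroundMetric(c=c)


def incidence_matrix(network: GeneNetwork) -> sp.csc_matrix:
    """Oriented node x edge incidence matrix D.

    Each undirected edge gets an arbitrary but fixed orientation: the
    endpoint with the smaller node index is the head (+1), the other the
    tail (-1). Columns follow the network's canonical edge ordering.
    """
    pairs = network.edge_index_pairs()
    m = pairs.shape[0]
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([np.arange(m), np.arange(m)])
    data = np.concatenate([np.ones(m), -np.ones(m)])
    return sp.csc_matrix((data, (rows, cols)), shape=(network.n_nodes, m))


def _as_prob(rho, n: int, name: str) -> np.ndarray:
    r = np.asarray(getattr(rho, "pi", rho), dtype=np.float64).ravel()
    if r.shape[0] != n:
        raise ValueError(f"{name}: length {r.shape[0]} does not match {n} nodes")
    if np.any(r < 0):
        raise ValueError(f"{name}: negative mass")
    return r


def _balance(rho0, rho1, n: int) -> tuple[np.ndarray, np.ndarray]:
    r0 = _as_prob(rho0, n, "rho0")
    r1 = _as_prob(rho1, n, "rho1")
    s0, s1 = r0.sum(), r1.sum()
    if abs(s0 - s1) > MASS_TOL:
        raise ValueError(
            f"unequal total masses: {s0!r} vs {s1!r} (difference beyond {MASS_TOL:g})"
        )
    if abs(s0 - 1.0) > MASS_TOL or abs(s1 - 1.0) > MASS_TOL:
        logger.warning(
            "input masses drift from 1 (%.3e, %.3e); renormalizing", s0 - 1, s1 - 1
        )
    return r0 / s0, r1 / s1


def _check_lp(res, context: str, residual: float) -> None:
    if res.status != 0:
        raise RuntimeError(f"{context}: LP solver failed ({res.message!r})")
    if residual > FEASIBILITY_TOL:
        raise RuntimeError(
            f"{context}: solution constraint residual {residual:.3e} exceeds "
            f"{FEASIBILITY_TOL:g}"
        )


def w1_flux(
    network: GeneNetwork, rho0, rho1, solver: str = "highs"
) -> tuple[float, FlowVector]:
    """W1 by the flux LP: min sum_e |u_e| subject to D u = rho0 - rho1.

    The absolute value is handled by the standard split u = u+ - u-,
    u+-, >= 0, objective sum(u+ + u-), keeping the problem a pure LP with
    2m nonnegative variables. This is the production path: its size scales
    with the edge count, not the squared node count.
    """
    network.require_connected("the flux transport LP")
    r0, r1 = _balance(rho0, rho1, network.n_nodes)
    d = incidence_matrix(network)
    m = d.shape[1]
    a_eq = sp.hstack([d, -d], format="csc")
    b_eq = r0 - r1
    res = linprog(
        c=np.ones(2 * m), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method=solver
    )
    if res.status == 2:  # infeasible cannot occur on connected balanced inputs
        raise RuntimeError(
            "flux LP reported infeasible on a connected graph with balanced "
            f"masses (solver: {res.message!r}); this indicates a solver fault"
        )
    u = res.x[:m] - res.x[m:] if res.x is not None else None
    residual = np.abs(d @ u - b_eq).max() if u is not None else np.inf
    _check_lp(res, "w1_flux", residual)
    return float(res.fun), FlowVector(u=u)


def w1_coupling(
    metric: GroundMetric, rho0, rho1, solver: str = "highs", max_nodes: int = COUPLING_MAX_NODES
) -> tuple[float, TransportPlan]:
    """W1 by the primal coupling LP (oracle; n^2 variables).

    Refuses instances above ``max_nodes`` — use :func:`w1_flux` there.
    """
    c = np.asarray(metric.c, dtype=np.float64)
    n = c.shape[0]
    if n > max_nodes:
        raise ValueError(
            f"coupling LP guard: {n} nodes > {max_nodes}; "
            "use w1_flux for large instances"
        )
    r0, r1 = _balance(rho0, rho1, n)
    eye = sp.eye(n, format="csr")
    ones = sp.csr_matrix(np.ones((1, n)))
    # row-sum constraints: (I kron 1^T) mu_vec = rho0 ; column sums: (1^T kron I)
    a_eq = sp.vstack([sp.kron(eye, ones), sp.kron(ones, eye)], format="csc")
    b_eq = np.concatenate([r0, r1])
    res = linprog(
        c=c.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method=solver
    )
    mu = res.x.reshape(n, n) if res.x is not None else None
    residual = (
        max(
            np.abs(mu.sum(axis=1) - r0).max(),
            np.abs(mu.sum(axis=0) - r1).max(),
        )
        if mu is not None
        else np.inf
    )
    _check_lp(res, "w1_coupling", residual)
    return float(res.fun), TransportPlan(mu=mu)


def w1_dual(
    network: GeneNetwork, rho0, rho1, solver: str = "highs"
) -> tuple[float, PotentialVector]:
    """W1 by the Kantorovich dual LP over node potentials.

    Maximizes f . (rho0 - rho1) subject to |f_i - f_j| <= 1 on every edge.
    The potential is only defined up to an additive constant; f at the
    first node is pinned to 0 to remove the degeneracy.
    """
    network.require_connected("the dual transport LP")
    r0, r1 = _balance(rho0, rho1, network.n_nodes)
    d = incidence_matrix(network)
    et = d.T.tocsr()  # edge x node; row e has +1 / -1 at the edge's endpoints
    a_ub = sp.vstack([et, -et], format="csc")
    b_ub = np.ones(2 * et.shape[0])
    bounds = [(0.0, 0.0)] + [(None, None)] * (network.n_nodes - 1)
    res = linprog(
        c=-(r0 - r1), A_ub=a_ub, b_ub=b_ub, bounds=bounds, method=solver
    )
    if res.status == 3:
        raise RuntimeError(
            "dual LP unbounded: the two measures carry unequal mass"
        )
    f = res.x if res.x is not None else None
    residual = max(0.0, float((np.abs(et @ f) - 1.0).max())) if f is not None else np.inf
    _check_lp(res, "w1_dual", residual)
    return float(-res.fun), PotentialVector(f=f)
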