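"""Shared interaction topology and per-sample expression containers.

The analysis operates on a single undirected gene–gene interaction network
shared by all samples, plus one strictly positive expression vector per
sample aligned to that network. This module owns both containers and the
preprocessing operations that reconcile a raw interaction list with an
expression table: restriction to common genes, duplicate-identifier
resolution, and extraction of the largest connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "ExpressionProfile",
    "restrict_to_common_genes",
    "largest_connected_component",
    "deduplicate_genes",
    "align_expression",
]


class GeneNetwork:
    """Undirected simple gene interaction graph with a fixed node ordering.

    Node order is the sorted list of gene identifiers; every vector or
    matrix produced downstream (expression, stationary measures, transport
    fluxes) uses this ordering, so serialized artifacts are reproducible
    across runs and platforms.

    Parameters
    ----------
    graph:
        ``networkx.Graph`` whose nodes are gene identifier strings.
        Self-loops are removed on ingest (the interaction databases this
        models contain self-interactions, which would silently distort the
        random walk); parallel edges cannot exist in ``nx.Graph``.
    """

    def __init__(self, graph: nx.Graph):
        g = nx.Graph(graph)  # copy; collapses any multi-edges
        n_loops = nx.number_of_selfloops(g)
        if n_loops:
            logger.warning("dropping %d self-loop(s) from interaction network", n_loops)
            g.remove_edges_from(nx.selfloop_edges(g))
        if g.number_of_nodes() == 0:
            raise ValueError("gene network has no nodes")
        self._graph = g
        self.node_ids: tuple[str, ...] = tuple(sorted(g.nodes, key=str))
        self.node_index: dict[str, int] = {gid: i for i, gid in enumerate(self.node_ids)}
        self._adjacency: sp.csr_matrix | None = None

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "GeneNetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edge_index_pairs(self) -> np.ndarray:
        """Edges as an (m, 2) int array of node indices with i < j, sorted.

        This fixed enumeration defines the edge ordering used by the
        incidence matrix and flux vectors.
        """
        pairs = sorted(
            tuple(sorted((self.node_index[a], self.node_index[b])))
            for a, b in self._graph.edges
        )
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency in the canonical node ordering (cached)."""
        if self._adjacency is None:
            self._adjacency = nx.to_scipy_sparse_array(
                self._graph, nodelist=list(self.node_ids), format="csr", dtype=np.float64
            ).tocsr()
        return self._adjacency

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel().astype(np.int64)

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self._graph)

    def require_connected(self, context: str = "this operation") -> None:
        if not self.is_connected:
            raise ValueError(
                f"{context} requires a connected network; "
                "take the largest connected component first"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.node_ids == other.node_ids and set(
            map(tuple, self.edge_index_pairs())
        ) == set(map(tuple, other.edge_index_pairs()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class ExpressionProfile:
    """One sample's strictly positive expression values, network-aligned.

    ``values[i]`` is the (already normalized, dimensionless) expression of
    gene ``network.node_ids[i]``. Positivity is a hard requirement of the
    mass-action edge weighting; violations raise with the offending gene
    named unless an explicit epsilon floor was configured upstream.
    """

    sample_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64).ravel()
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite expression values")

    def validate_against(self, network: GeneNetwork) -> None:
        if self.values.shape[0] != network.n_nodes:
            raise ValueError(
                f"sample {self.sample_id!r}: {self.values.shape[0]} values for "
                f"{network.n_nodes} network genes"
            )
        bad = np.flatnonzero(self.values <= 0)
        if bad.size:
            gene = network.node_ids[bad[0]]
            raise ValueError(
                f"sample {self.sample_id!r}: non-positive expression for gene "
                f"{gene!r} ({self.values[bad[0]]!r}); mass-action weights require "
                "strictly positive values (configure epsilon_floor to floor them)"
            )


def restrict_to_common_genes(
    network: GeneNetwork, expression_gene_ids: Sequence[str]
) -> GeneNetwork:
    """Induce the network on genes present in both the topology and the
    expression table, dropping nodes left without any edge.

    Raises ``ValueError`` when the two gene universes do not intersect.
    """
    if network.n_nodes == 0 or len(expression_gene_ids) == 0:
        raise ValueError("restrict_to_common_genes: empty input")
    common = set(network.node_ids) & set(map(str, expression_gene_ids))
    if not common:
        raise ValueError(
            "no genes shared between the interaction network "
            f"({network.n_nodes} genes) and the expression table "
            f"({len(set(expression_gene_ids))} genes)"
        )
    sub = network.graph.subgraph(common).copy()
    isolated = list(nx.isolates(sub))
    if isolated:
        logger.info("dropping %d gene(s) left without interactions", len(isolated))
        sub.remove_nodes_from(isolated)
    if sub.number_of_nodes() == 0:
        raise ValueError("restriction to common genes left no connected genes")
    return GeneNetwork(sub)


def largest_connected_component(network: GeneNetwork) -> GeneNetwork:
    """Return the component with the most nodes.

    Ties are broken by the lexicographically smallest member gene id so the
    result is deterministic across runs and platforms.
    """
    if network.n_nodes == 0:
        raise ValueError("largest_connected_component: empty network")
    components = [sorted(c) for c in nx.connected_components(network.graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return GeneNetwork(network.graph.subgraph(components[0]).copy())


def deduplicate_genes(
    gene_ids: Sequence[str],
    values: np.ndarray,
    policy: str = "error",
) -> tuple[list[str], np.ndarray]:
    """Resolve duplicate gene identifiers in an expression matrix.

    ``values`` is row-aligned to ``gene_ids`` (rows = genes, columns =
    samples). ``policy`` is one of ``error`` (default: duplicates are a data
    bug), ``first``, ``sum`` or ``max``; the non-error policies combine the
    duplicate rows accordingly. First-occurrence order of ids is preserved.
    """
    if policy not in {"error", "first", "sum", "max"}:
        raise ValueError(f"unknown deduplication policy {policy!r}")
    gene_ids = [str(g) for g in gene_ids]
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if values.shape[0] != len(gene_ids):
        raise ValueError("values must be row-aligned to gene_ids")
    seen: dict[str, list[int]] = {}
    for i, g in enumerate(gene_ids):
        seen.setdefault(g, []).append(i)
    dups = {g: idx for g, idx in seen.items() if len(idx) > 1}
    if not dups:
        return list(gene_ids), values
    if policy == "error":
        names = ", ".join(sorted(dups)[:5])
        raise ValueError(
            f"{len(dups)} duplicate gene identifier(s) (e.g. {names}); "
            "set an explicit deduplication policy (first/sum/max) to combine them"
        )
    reducers = {"first": lambda m: m[0], "sum": lambda m: m.sum(axis=0), "max": lambda m: m.max(axis=0)}
    out_ids = list(seen)  # first-occurrence order (dict preserves insertion)
    out = np.vstack([reducers[policy](values[seen[g], :]) for g in out_ids])
    logger.warning("combined %d duplicate gene id(s) with policy=%s", len(dups), policy)
    return out_ids, out


def align_expression(
    network: GeneNetwork,
    gene_ids: Sequence[str],
    values: np.ndarray,
    sample_id: str,
    epsilon_floor: float | None = None,
) -> ExpressionProfile:
    """Reorder one sample's expression vector to the network node ordering.

    Every network gene must be present. When ``epsilon_floor`` is given,
    non-positive entries are replaced by ``epsilon_floor`` times the smallest
    positive value (audited with a warning); otherwise positivity is enforced.
    """
    index = {str(g): i for i, g in enumerate(gene_ids)}
    missing = [g for g in network.node_ids if g not in index]
    if missing:
        raise ValueError(
            f"sample {sample_id!r}: expression missing {len(missing)} network "
            f"gene(s), e.g. {missing[:5]}"
        )
    v = np.asarray(values, dtype=np.float64).ravel()
    x = v[[index[g] for g in network.node_ids]].copy()
    if epsilon_floor is not None:
        nonpos = x <= 0
        if nonpos.any():
            pos_min = x[~nonpos].min() if (~nonpos).any() else 1.0
            floor = epsilon_floor * pos_min
            logger.warning(
                "sample %r: flooring %d non-positive value(s) to %.3g",
                sample_id, int(nonpos.sum()), floor,
            )
            x[nonpos] = floor
    profile = ExpressionProfile(sample_id=sample_id, values=x)
    profile.validate_against(network)
    return profile
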