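"""Cohort-level analysis of pairwise Wasserstein-1 distances.

Given one invariant measure per sample on the shared network, this module
assembles the symmetric pairwise W1 matrix, binarizes it at a threshold
(zero when the distance is strictly less than the threshold, one
otherwise), reads clusters off the resulting closeness graph as connected
components, summarizes within- and between-group distances, and flags
outliers whose mean distance to the rest of the cohort is extreme.

The clustering and outlier rules are deliberately simple, explicit
formalizations of what a reader takes from a thresholded heat map: the
original analysis identified clusters and its outlier visually; committing
to connected components and a mean + k.SD rule makes the same calls
algorithmic and testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .markov import InvariantMeasure
from .network import GeneNetwork
from .transport import w1_flux

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "CohortSummary",
    "pairwise_distance_matrix",
    "binarize_threshold",
    "extract_clusters",
    "cohort_summary",
    "flag_outliers",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distance matrix over a cohort."""

    sample_ids: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self):
        d = np.asarray(self.d, dtype=np.float64)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} vs {n} sample ids")
        if np.abs(d - d.T).max() > 1e-8:
            raise ValueError("distance matrix is not symmetric within 1e-8")
        if np.abs(np.diag(d)).max() > 1e-9:
            raise ValueError("distance matrix diagonal is not zero")
        if d.min() < 0:
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class CohortSummary:
    """Within/between-group mean distances and per-sample means.

    ``within_mean[g]`` is None for groups with fewer than two members
    (no pairs to average).
    """

    within_mean: dict[str, float | None]
    between_mean: float | None
    per_sample_mean: dict[str, float]


def pairwise_distance_matrix(
    network: GeneNetwork,
    measures: list[InvariantMeasure],
    solver: str = "highs",
    n_jobs: int = 1,
    progress: bool = False,
) -> DistanceMatrix:
    """Solve the flux LP for every unordered sample pair.

    Only the upper triangle is solved; each pair is an independent LP with
    deterministic solver settings, so results do not depend on execution
    order and the solves may run in parallel (``n_jobs``).
    """
    if len(measures) < 2:
        raise ValueError("need at least 2 measures for a distance matrix")
    ids = tuple(m.sample_id for m in measures)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in cohort")
    n = len(measures)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def solve(i: int, j: int) -> float:
        try:
            dist, _ = w1_flux(network, measures[i], measures[j], solver=solver)
        except Exception as exc:
            raise RuntimeError(
                f"pairwise W1 failed for ({ids[i]!r}, {ids[j]!r}): {exc}"
            ) from exc
        return dist

    if n_jobs == 1:
        values = []
        for k, (i, j) in enumerate(pairs):
            values.append(solve(i, j))
            if progress and (k + 1) % 100 == 0:
                logger.info("solved %d/%d pairs", k + 1, len(pairs))
    else:
        values = Parallel(n_jobs=n_jobs)(delayed(solve)(i, j) for i, j in pairs)

    d = np.zeros((n, n))
    for (i, j), v in zip(pairs, values):
        d[i, j] = d[j, i] = v
    return DistanceMatrix(sample_ids=ids, d=d)


def binarize_threshold(d: DistanceMatrix, threshold: float) -> np.ndarray:
    """Truncate distances: 0 where d < threshold (strictly), 1 otherwise.

    The strict inequality means a distance exactly at the threshold maps
    to 1. Note the diagonal (distance 0) always maps to 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return (d.d >= threshold).astype(np.int8)


def extract_clusters(d: DistanceMatrix, threshold: float) -> dict[str, int]:
    """Clusters = connected components of the closeness graph.

    Two samples are adjacent when their distance is strictly below the
    threshold (binarized value 0). Clusters are numbered 0, 1, ... by their
    smallest member index, so the labeling is deterministic. Singletons are
    allowed.
    """
    close = binarize_threshold(d, threshold) == 0
    np.fill_diagonal(close, False)
    n_comp, raw = connected_components(csr_matrix(close), directed=False)
    # renumber components by smallest member index
    order = {}
    for idx in raw:
        if idx not in order:
            order[idx] = len(order)
    return {sid: order[raw[i]] for i, sid in enumerate(d.sample_ids)}


def cohort_summary(d: DistanceMatrix, labels: dict[str, str]) -> CohortSummary:
    """Mean distance within each group, between groups, and per sample.

    Means are over unordered pairs. A group with a single member has no
    within pairs; its mean is reported as missing (None). The between mean
    covers every pair whose two samples carry different labels.
    """
    missing = [s for s in d.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for sample(s) {missing[:5]}")
    lab = np.array([labels[s] for s in d.sample_ids])
    groups = sorted(set(lab))
    iu = np.triu_indices(d.n, k=1)
    same = lab[iu[0]] == lab[iu[1]]
    vals = d.d[iu]

    within: dict[str, float | None] = {}
    for g in groups:
        mask = same & (lab[iu[0]] == g)
        within[g] = float(vals[mask].mean()) if mask.any() else None
    between = float(vals[~same].mean()) if (~same).any() else None
    per_sample = {
        s: float((d.d[i].sum()) / (d.n - 1)) for i, s in enumerate(d.sample_ids)
    }
    return CohortSummary(within_mean=within, between_mean=between, per_sample_mean=per_sample)


def flag_outliers(d: DistanceMatrix, k: float = 2.0) -> list[str]:
    """Samples whose mean distance to all others is > cohort mean + k.SD.

    The mean and standard deviation are taken over the per-sample mean
    distances. A zero-spread cohort (constant matrix) flags nothing.
    """
    if d.n < 3:
        raise ValueError("outlier flagging needs at least 3 samples")
    means = d.d.sum(axis=1) / (d.n - 1)
    sd = means.std()
    if sd == 0:
        return []
    cut = means.mean() + k * sd
    return [s for i, s in enumerate(d.sample_ids) if means[i] > cut]
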