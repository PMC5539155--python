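"""scikit-learn-style estimators over the transport pipeline.

These classes expose the pipeline's stages in the fit/transform/predict
idiom so they compose with sklearn tooling (pipelines, model selection on
precomputed distances):

* :class:`MassActionMeasures` — transformer mapping an expression matrix
  (samples x genes, strictly positive) to stationary measures of the
  per-sample mass-action walk on a fixed interaction network.
* :class:`GraphWasserstein` — transformer mapping stationary measures to
  W1 distances against a fitted reference set; ``fit_transform`` yields
  the symmetric pairwise cohort matrix.
* :class:`ThresholdClustering` — clusterer on a precomputed distance
  matrix: connected components of the graph joining pairs closer than the
  threshold.
* :class:`MeanDistanceOutlierDetector` — outlier detector on a precomputed
  distance matrix: flags samples whose mean distance to the rest exceeds
  the cohort mean by k standard deviations.

The module-level functions in :mod:`graphemd.cohort` and
:mod:`graphemd.markov` are the primitive operations these wrap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, OutlierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .cohort import DistanceMatrix, extract_clusters, flag_outliers, pairwise_distance_matrix
from .markov import InvariantMeasure, stationary_closed_form
from .network import GeneNetwork, align_expression
from .transport import w1_flux

__all__ = [
    "MassActionMeasures",
    "GraphWasserstein",
    "ThresholdClustering",
    "MeanDistanceOutlierDetector",
]


def _check_square_distances(X) -> np.ndarray:
    X = check_array(X, ensure_min_samples=2)
    if X.shape[0] != X.shape[1]:
        raise ValueError(f"expected a square precomputed distance matrix, got {X.shape}")
    return X


class MassActionMeasures(TransformerMixin, BaseEstimator):
    """Transform expression profiles into stationary measures.

    Parameters
    ----------
    network:
        The shared :class:`~graphemd.network.GeneNetwork`. Must be
        connected.
    epsilon_floor:
        When set, non-positive expression entries are floored to this
        multiple of the sample's smallest positive value instead of
        raising.

    Attributes
    ----------
    node_ids_ : tuple of str
        Gene ordering of the output columns (the network's canonical
        ordering).
    """

    def __init__(self, network: GeneNetwork = None, epsilon_floor: float | None = None):
        self.network = network
        self.epsilon_floor = epsilon_floor

    def fit(self, X=None, y=None):
        if self.network is None:
            raise ValueError("MassActionMeasures requires a network")
        self.network.require_connected("the stationary measure")
        self.node_ids_ = self.network.node_ids
        return self

    def transform(self, X) -> np.ndarray:
        """Rows of X are samples; columns align to the network genes.

        A DataFrame may carry arbitrary gene columns (matched by name);
        a bare array must already follow ``node_ids_``. Returns the
        (n_samples, n_genes) matrix of stationary probability vectors.
        """
        check_is_fitted(self)
        if isinstance(X, pd.DataFrame):
            gene_ids = [str(g) for g in X.columns]
            sample_ids = [str(s) for s in X.index]
            values = X.to_numpy(dtype=np.float64)
        else:
            values = check_array(X)
            if values.shape[1] != len(self.node_ids_):
                raise ValueError(
                    f"{values.shape[1]} columns for {len(self.node_ids_)} network genes"
                )
            gene_ids = list(self.node_ids_)
            sample_ids = [str(i) for i in range(values.shape[0])]
        out = np.empty((values.shape[0], len(self.node_ids_)))
        for k, sid in enumerate(sample_ids):
            profile = align_expression(
                self.network, gene_ids, values[k], sid, epsilon_floor=self.epsilon_floor
            )
            out[k] = stationary_closed_form(self.network, profile).pi
        return out


class GraphWasserstein(TransformerMixin, BaseEstimator):
    """W1 distances between stationary measures on the fitted network.

    ``fit(Pi)`` stores a reference set of measures; ``transform(Q)``
    returns the (len(Q), len(Pi)) matrix of distances to the reference.
    ``fit_transform(Pi)`` solves only the upper triangle and returns the
    symmetric cohort matrix.
    """

    def __init__(self, network: GeneNetwork = None, solver: str = "highs", n_jobs: int = 1):
        self.network = network
        self.solver = solver
        self.n_jobs = n_jobs

    def _validate(self, X) -> np.ndarray:
        X = check_array(X)
        if X.shape[1] != self.network.n_nodes:
            raise ValueError(f"{X.shape[1]} columns for {self.network.n_nodes} nodes")
        return X

    def fit(self, X, y=None):
        if self.network is None:
            raise ValueError("GraphWasserstein requires a network")
        self.reference_ = self._validate(X)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = self._validate(X)
        out = np.empty((X.shape[0], self.reference_.shape[0]))
        for i in range(X.shape[0]):
            for j in range(self.reference_.shape[0]):
                out[i, j], _ = w1_flux(
                    self.network, X[i], self.reference_[j], solver=self.solver
                )
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        measures = [
            InvariantMeasure(sample_id=str(i), pi=row) for i, row in enumerate(self.reference_)
        ]
        return pairwise_distance_matrix(
            self.network, measures, solver=self.solver, n_jobs=self.n_jobs
        ).d


class ThresholdClustering(ClusterMixin, BaseEstimator):
    """Connected-components clustering of a precomputed distance matrix.

    Samples closer than ``threshold`` (strictly) are joined; clusters are
    the components, numbered by smallest member index. Raising the
    threshold merges clusters, never splits them.
    """

    def __init__(self, threshold: float = 0.075):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = _check_square_distances(X)
        dm = DistanceMatrix(sample_ids=tuple(str(i) for i in range(X.shape[0])), d=X)
        assignment = extract_clusters(dm, self.threshold)
        self.labels_ = np.array([assignment[s] for s in dm.sample_ids])
        self.n_clusters_ = int(self.labels_.max()) + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class MeanDistanceOutlierDetector(OutlierMixin, BaseEstimator):
    """Mean-distance outlier rule on a precomputed distance matrix.

    A sample is an outlier (prediction -1) when its mean distance to all
    other samples exceeds the cohort mean of those per-sample means by
    more than ``k`` standard deviations.
    """

    def __init__(self, k: float = 2.0):
        self.k = k

    def fit(self, X, y=None):
        X = _check_square_distances(X)
        dm = DistanceMatrix(sample_ids=tuple(str(i) for i in range(X.shape[0])), d=X)
        flagged = set(flag_outliers(dm, k=self.k))
        self.mean_distances_ = X.sum(axis=1) / (X.shape[0] - 1)
        self.outlier_mask_ = np.array([s in flagged for s in dm.sample_ids])
        return self

    def predict(self, X=None):
        check_is_fitted(self)
        return np.where(self.outlier_mask_, -1, 1)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict()
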