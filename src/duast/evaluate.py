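"""Clustering of the fused embeddings and evaluation metrics.

Spatial domains are inferred from the fused embedding with a
tied-covariance Gaussian mixture (the EEE model of mclust-style
model-based clustering: equal volume, shape and orientation), fitted by
EM with k-means initialization and multiple restarts.  Agreement with
reference annotations is reported with the standard partition metrics;
internal quality with silhouette and Davies-Bouldin; spatial
autocorrelation of gene patterns with Moran's I under row-standardized
KNN weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict

import numpy as np
from sklearn import metrics as skm
from sklearn.mixture import GaussianMixture

from .graph import SpatialGraph

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    labels: np.ndarray
    n_clusters: int
    model_loglik: float
    restarts_used: int


def cluster_embeddings(Z: np.ndarray, n_clusters: int, seed: int = 0,
                       restarts: int = 10) -> ClusterResult:
    """Tied-covariance Gaussian-mixture clustering of embeddings.

    EM with k-means initialization, best of ``restarts`` by
    log-likelihood, deterministic under a fixed seed.  A singular
    covariance triggers one retry with a stronger diagonal
    regularization before erroring.
    """
    Z = np.asarray(Z, dtype=float)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if Z.shape[0] <= n_clusters:
        raise ValueError("need more observations than clusters")

    for reg in (1e-6, 1e-3):
        try:
            gm = GaussianMixture(n_components=n_clusters,
                                 covariance_type="tied",
                                 init_params="kmeans", n_init=restarts,
                                 tol=1e-6, reg_covar=reg, max_iter=300,
                                 random_state=seed)
            labels = gm.fit_predict(Z)
            break
        except (ValueError, np.linalg.LinAlgError) as err:  # degenerate EM
            last_err = err
    else:
        raise RuntimeError(f"EM failed even with regularization: {last_err}")

    counts = np.bincount(labels, minlength=n_clusters)
    if np.any(counts == 0):
        logger.warning("empty clusters: %s", np.flatnonzero(counts == 0))
    return ClusterResult(labels=labels, n_clusters=n_clusters,
                         model_loglik=float(gm.score(Z) * Z.shape[0]),
                         restarts_used=restarts)


def morans_i(values: np.ndarray, graph: SpatialGraph) -> float:
    """Moran's I spatial autocorrelation under row-standardized weights.

    ``I = (N / sum(W)) * sum_ij w_ij (x_i - xbar)(x_j - xbar)
    / sum_i (x_i - xbar)^2``; NaN (with a warning) for a constant
    vector, where the statistic is undefined.
    """
    x = np.asarray(values, dtype=float)
    N = x.size
    if graph.n_spots != N:
        raise ValueError("value vector does not match the graph size")
    xc = x - x.mean()
    denom = np.sum(xc ** 2)
    if denom == 0:
        warnings.warn("Moran's I undefined for a constant vector",
                      RuntimeWarning)
        return float("nan")
    deg = graph.A.sum(axis=1, keepdims=True)
    deg[deg == 0] = 1.0
    W = graph.A / deg                      # row-standardized
    num = xc @ W @ xc
    return float((N / W.sum()) * num / denom)


def supervised_metrics(pred: np.ndarray, truth: np.ndarray) -> Dict[str, float]:
    """The seven partition-agreement metrics (label-permutation
    invariant): MI, NMI, AMI, V-measure, completeness, ARI, FMI."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth have different lengths")
    return {
        "MI": float(skm.mutual_info_score(truth, pred)),
        "NMI": float(skm.normalized_mutual_info_score(truth, pred)),
        "AMI": float(skm.adjusted_mutual_info_score(truth, pred)),
        "VMeasure": float(skm.v_measure_score(truth, pred)),
        "Completeness": float(skm.completeness_score(truth, pred)),
        "ARI": float(skm.adjusted_rand_score(truth, pred)),
        "FMI": float(skm.fowlkes_mallows_score(truth, pred)),
    }


def unsupervised_metrics(Z: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Silhouette coefficient (Euclidean) and Davies-Bouldin index."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("internal metrics require at least two clusters")
    return (float(skm.silhouette_score(Z, labels)),
            float(skm.davies_bouldin_score(Z, labels)))
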