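"""Multi-restart k-means and the decrease-in-overall-deviation statistic.

Clustering runs in the z-scaled space of the selected covariates over the
pooled current + subject + candidate locations.  Each restart of Lloyd's
algorithm initializes the K centers at distinct data rows, iterates
(assign to nearest center, recompute means) until the assignment is stable,
and the restart with the lowest total within-cluster sum of squares (SSW)
wins.

Cluster-count choice is guided by the decrease in overall deviation

    DiD(%) = 100 × (1 − (1/J) Σ_j Σ_k SSW_jk / SSE_j)

over J characteristics: SSW_jk is the within-cluster sum of squared
deviations of characteristic j in cluster k, SSE_j the total sum of squared
deviations about the grand mean.  DiD is 0 for a single cluster, 100 when
every location is its own cluster, and rises to a plateau as k grows; the
start of the plateau — evaluated consistently on two characteristic sets,
the predicted concentrations (J = 1) and the selected covariates
(J = 5) — suggests k.  The suggestion is advisory; the pipeline accepts a
user-fixed k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["ClusterSolution", "DidCurve", "kmeans_best", "did", "did_curve",
           "suggest_k", "cluster_profiles"]


@dataclass
class ClusterSolution:
    """Best-of-restarts k-means solution on one data matrix."""

    K: int
    assignment: np.ndarray            # cluster index per location
    centers: np.ndarray               # K x J, scaled covariate space
    ssw_per_cluster_per_characteristic: np.ndarray  # K x J
    total_ssw: float
    n_iterations: int
    restart_index: int
    ssw_history: list[float] = field(default_factory=list)


@dataclass
class DidCurve:
    k_values: np.ndarray
    did_predictions: np.ndarray       # J = 1 characteristic
    did_covariates: np.ndarray        # J = number of clustering covariates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values,
                             "did_predictions": self.did_predictions,
                             "did_covariates": self.did_covariates})


def _ssw_matrix(X: np.ndarray, assignment: np.ndarray, K: int) -> np.ndarray:
    """SSW_kj: within-cluster sum of squared deviations, per cluster/column."""
    out = np.zeros((K, X.shape[1]))
    for k in range(K):
        mem = X[assignment == k]
        if len(mem):
            out[k] = ((mem - mem.mean(axis=0)) ** 2).sum(axis=0)
    return out


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300,
           ) -> tuple[np.ndarray, np.ndarray, int, list[float]]:
    """Lloyd iterations from given centers until the assignment is stable.

    Returns (assignment, centers, n_iterations, per-iteration total SSW).
    The SSW history is measured against cluster means after each update
    step and is non-increasing.
    """
    K = len(centers)
    assignment = None
    history: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centers, "sqeuclidean")
        new_assignment = d2.argmin(axis=1)
        for k in range(K):
            mem = new_assignment == k
            if mem.any():
                centers[k] = X[mem].mean(axis=0)
            else:
                # empty cluster: reseed at the point farthest from its center
                worst = d2[np.arange(len(X)), new_assignment].argmax()
                centers[k] = X[worst]
                new_assignment[worst] = k
        history.append(float(
            ((X - centers[new_assignment]) ** 2).sum()))
        if assignment is not None and np.array_equal(assignment, new_assignment):
            assignment = new_assignment
            break
        assignment = new_assignment
    return assignment, centers, it, history


def kmeans_best(X_scaled: np.ndarray | pd.DataFrame, K: int,
                n_restarts: int = 1000, seed: int = 0,
                keep_history: bool = False) -> ClusterSolution:
    """Best of ``n_restarts`` Lloyd runs by total SSW.

    Each restart draws K distinct data rows as initial centers from a
    single seeded generator, so the whole search is reproducible.
    """
    X = np.asarray(X_scaled, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) == 0:
        raise ValueError("empty input")
    unique_rows = np.unique(X, axis=0)
    if not 1 <= K <= len(unique_rows):
        raise ValueError(f"K={K} outside [1, {len(unique_rows)} distinct rows]")

    rng = np.random.default_rng(seed)
    best: ClusterSolution | None = None
    for r in range(n_restarts):
        # K distinct data rows as initial centers
        init = rng.choice(len(unique_rows), size=K, replace=False)
        assignment, centers, n_iter, history = _lloyd(X, unique_rows[init].copy())
        total = history[-1]
        if best is None or total < best.total_ssw:
            ssw = _ssw_matrix(X, assignment, K)
            best = ClusterSolution(
                K=K, assignment=assignment, centers=centers,
                ssw_per_cluster_per_characteristic=ssw,
                total_ssw=float(ssw.sum()), n_iterations=n_iter,
                restart_index=r,
                ssw_history=history if keep_history else [])
    return best


def did(assignment: np.ndarray, Y: np.ndarray | pd.DataFrame) -> float:
    """Decrease in overall deviation (%) of a partition for characteristics Y.

    ``Y`` is locations × J; each characteristic contributes its within- to
    total-deviation ratio Σ_k SSW_jk / SSE_j, and DiD is 100 × (1 − mean of
    those ratios).  A constant characteristic (SSE_j = 0) is an error.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    assignment = np.asarray(assignment)
    if len(assignment) != len(Y):
        raise ValueError("assignment does not cover all rows of Y")
    sse = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(sse == 0):
        bad = np.nonzero(sse == 0)[0].tolist()
        raise ValueError(f"constant characteristic column(s) {bad}")
    K = assignment.max() + 1
    ssw = _ssw_matrix(Y, assignment, K).sum(axis=0)
    return float(100.0 * (1.0 - np.mean(ssw / sse)))


def did_curve(X_scaled: np.ndarray | pd.DataFrame,
              predictions: np.ndarray | pd.Series,
              k_max: int = 50, n_restarts: int = 1000, seed: int = 0,
              ) -> DidCurve:
    """DiD against k for k = 1..k_max.

    Clustering always runs on the scaled covariates; each solution is then
    scored twice — once with the predicted concentrations as the single
    characteristic, once with the covariates themselves.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = np.asarray(X_scaled, dtype=float)
    preds = np.asarray(predictions, dtype=float)
    ks = np.arange(1, k_max + 1)
    d_pred = np.empty(len(ks))
    d_cov = np.empty(len(ks))
    seeds = np.random.SeedSequence(seed).generate_state(len(ks)) % (2 ** 31)
    for i, k in enumerate(ks):
        sol = kmeans_best(X, int(k), n_restarts=n_restarts, seed=int(seeds[i]))
        d_pred[i] = did(sol.assignment, preds)
        d_cov[i] = did(sol.assignment, X)
    return DidCurve(k_values=ks, did_predictions=d_pred, did_covariates=d_cov)


def suggest_k(curve: DidCurve, marginal_gain_threshold: float = 1.0,
              lookahead: int = 3) -> int:
    """Smallest k at the start of the plateau of both DiD curves.

    A k qualifies when every forward marginal gain over the next
    ``lookahead`` steps (as far as the curve extends) stays below the
    threshold, in percentage points, for both characteristic sets.
    Advisory only; falls back to k_max with a warning when no plateau is
    found, and never suggests below 2.
    """
    ks = curve.k_values
    # the last k has no forward gain to inspect, so it cannot confirm a
    # plateau; reaching it means falling back
    for idx in range(len(ks) - 1):
        if ks[idx] < 2:
            continue
        ok = True
        for c in (curve.did_predictions, curve.did_covariates):
            gains = np.diff(c[idx: idx + lookahead + 1])
            if gains.max() >= marginal_gain_threshold:
                ok = False
                break
        if ok:
            return int(ks[idx])
    warnings.warn("no DiD plateau below the threshold; falling back to k_max")
    return int(ks[-1])


def cluster_profiles(assignment: np.ndarray,
                     X_scaled: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """K × J matrix of within-cluster means of the scaled covariates.

    This is the heatmap body used to characterize clusters; rows are
    clusters, columns covariates.  An empty cluster is an error.
    """
    cols = (list(X_scaled.columns) if isinstance(X_scaled, pd.DataFrame)
            else [f"var_{j}" for j in range(np.asarray(X_scaled).shape[1])])
    X = np.asarray(X_scaled, dtype=float)
    assignment = np.asarray(assignment)
    K = assignment.max() + 1
    rows = []
    for k in range(K):
        mem = X[assignment == k]
        if not len(mem):
            raise ValueError(f"cluster {k} is empty")
        rows.append(mem.mean(axis=0))
    return pd.DataFrame(rows, columns=cols,
                        index=pd.RangeIndex(K, name="cluster"))
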