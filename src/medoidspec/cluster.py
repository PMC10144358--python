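"""K-medoids (PAM) clustering of feature matrices.

The loss minimized is the sum over frames of the *squared* Euclidean
distance to the assigned cluster center, with centers constrained to be
dataset members (medoids). BUILD greedily seeds the medoid set; SWAP then
performs first-improvement medoid/non-medoid exchanges in deterministic
index order until no single swap strictly lowers the loss. Multiple
restarts (the first from BUILD, the rest from seeded random initial sets)
guard against local minima; results are bit-reproducible given the seed.

The number of clusters is chosen by scanning K, reading an inertia elbow
(maximum second difference) and the Calinski-Harabasz index; when the two
diagnostics disagree the CH maximum wins, and both are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import calinski_harabasz_score

logger = logging.getLogger(__name__)

_SWAP_TOL = 1e-12


@dataclass
class Clustering:
    """A K-medoids solution: labels, medoid frame indices, loss, populations."""

    K: int
    labels: np.ndarray
    medoid_indices: np.ndarray
    inertia: float
    populations: np.ndarray

    def __post_init__(self) -> None:
        assert abs(self.populations.sum() - 1.0) < 1e-12


@dataclass
class KSelectionReport:
    """Diagnostics of a K scan: inertia and CH per K, chosen K and rule."""

    k_values: list[int]
    inertias: list[float]
    ch_scores: list[float]
    chosen_k: int
    elbow_k: int | None
    rule: str = "calinski_harabasz_argmax"
    solutions: dict[int, Clustering] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": self.k_values, "inertia": self.inertias, "calinski_harabasz": self.ch_scores}
        )


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.select_dtypes(include=[np.number])
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def _sq_dist_matrix(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(X, metric="sqeuclidean"))


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Assign each point to its nearest medoid (ties to the lowest index)."""
    sub = D[:, medoids]  # medoids kept sorted => argmin first-hit = lowest index
    labels = np.argmin(sub, axis=1)
    loss = float(sub[np.arange(len(D)), labels].sum())
    return labels, loss


def _build_init(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD seeding: each new medoid maximally reduces the loss."""
    n = len(D)
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    d_near = D[:, first].copy()
    while len(medoids) < k:
        new_loss = np.minimum(D, d_near[:, None]).sum(axis=0)
        new_loss[medoids] = np.inf
        j = int(np.argmin(new_loss))
        medoids.append(j)
        d_near = np.minimum(d_near, D[:, j])
    return np.sort(np.asarray(medoids))


def _swap_phase(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, int]:
    """First-improvement SWAP passes; strict decrease guarantees termination."""
    n = len(D)
    medoids = np.sort(medoids.copy())
    n_swaps = 0
    improved = True
    while improved:
        improved = False
        sub = D[:, medoids]
        order = np.argsort(sub, axis=1)
        near_pos = order[:, 0]
        d1 = sub[np.arange(n), near_pos]
        d2 = sub[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        candidates = np.flatnonzero(~is_medoid)
        for pos in range(len(medoids)):
            # cost of removing medoid `pos`: points it serves fall back to d2
            t = np.where(near_pos == pos, d2, d1)
            # delta(h) for all candidate replacements h at once
            delta = np.minimum(D[:, candidates], t[:, None]).sum(axis=0) - d1.sum()
            better = np.flatnonzero(delta < -_SWAP_TOL)
            if better.size:
                h = candidates[better[0]]  # first improvement, deterministic order
                medoids[pos] = h
                medoids = np.sort(medoids)
                n_swaps += 1
                improved = True
                break
    return medoids, n_swaps


class KMedoids(ClusterMixin, BaseEstimator):
    """PAM K-medoids clusterer with squared-Euclidean loss.

    Parameters
    ----------
    n_clusters : number of clusters K.
    n_restarts : optimization restarts; the first uses BUILD seeding, the
        rest random initial medoid sets drawn from ``random_state``.
        The best (lowest-loss) solution is kept, ties broken by the
        lexicographically smallest medoid set.
    random_state : seed for the random restarts (required for n_restarts > 1).
    warm_start_medoids : optional explicit initial medoid set; when given it
        is optimized by SWAP as an additional restart.

    Attributes (after ``fit``)
    ----------
    labels_ : (N,) cluster index per frame.
    medoid_indices_ : (K,) dataset indices of the cluster centers.
    inertia_ : value of the squared-distance loss at the solution.
    populations_ : (K,) cluster population fractions p_k = N_k / N.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_restarts: int = 8,
        random_state: int | None = None,
        warm_start_medoids=None,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.warm_start_medoids = warm_start_medoids

    def fit(self, X, y=None):
        X = _as_array(X)
        n = len(X)
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters {k} outside [1, {n}]")
        col_std = X.std(axis=0)
        if col_std.size and (np.abs(X.mean(axis=0)).max() > 0.1 or
                             (col_std > 0).any() and abs(col_std[col_std > 0].mean() - 1) > 0.5):
            logger.warning("features do not look standardized; distances may be dominated by scale")
        D = _sq_dist_matrix(X)
        self._fit_precomputed(D)
        self._medoid_points_ = X[self.medoid_indices_]
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_precomputed(self, D: np.ndarray) -> None:
        n = len(D)
        k = self.n_clusters
        if k == n:
            medoids = np.arange(n)
            labels, loss = _assign(D, medoids)
            best = (loss, tuple(medoids), medoids, labels)
        else:
            inits = [_build_init(D, k)]
            if self.warm_start_medoids is not None:
                ws = np.sort(np.asarray(self.warm_start_medoids, dtype=int))
                if len(ws) != k or len(np.unique(ws)) != k:
                    raise ValueError("warm_start_medoids must be K distinct indices")
                inits.append(ws)
            n_random = max(self.n_restarts - 1, 0)
            if n_random:
                if self.random_state is None:
                    raise ValueError("random_state is required for n_restarts > 1")
                rng = np.random.default_rng(self.random_state)
                for _ in range(n_random):
                    inits.append(np.sort(rng.choice(n, size=k, replace=False)))
            best = None
            for init in inits:
                medoids, _ = _swap_phase(D, init)
                labels, loss = _assign(D, medoids)
                key = (loss, tuple(medoids))
                if best is None or key < (best[0], best[1]):
                    best = (loss, tuple(medoids), medoids, labels)
        loss, _, medoids, labels = best
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = loss
        self.populations_ = np.bincount(labels, minlength=k) / n

    def predict(self, X) -> np.ndarray:
        X = _as_array(X)
        from scipy.spatial.distance import cdist

        d = cdist(X, self._medoid_points_, metric="sqeuclidean")
        return np.argmin(d, axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def pam(
    feature_matrix,
    k: int,
    seed: int | None = None,
    n_restarts: int = 8,
    warm_start_medoids=None,
) -> Clustering:
    """Cluster a feature matrix into K clusters by PAM; see :class:`KMedoids`."""
    est = KMedoids(
        n_clusters=k, n_restarts=n_restarts, random_state=seed, warm_start_medoids=warm_start_medoids
    )
    est.fit(feature_matrix)
    return Clustering(
        K=k,
        labels=est.labels_,
        medoid_indices=est.medoid_indices_,
        inertia=est.inertia_,
        populations=est.populations_,
    )


def inertia(feature_matrix, labels, medoid_indices) -> float:
    """Sum of squared distances from each point to its cluster's medoid."""
    X = _as_array(feature_matrix)
    labels = np.asarray(labels, dtype=int)
    medoid_indices = np.asarray(medoid_indices, dtype=int)
    if labels.max() >= len(medoid_indices):
        raise ValueError("label references a missing medoid")
    centers = X[medoid_indices[labels]]
    return float(((X - centers) ** 2).sum())


def populations(labels) -> np.ndarray:
    """Cluster population fractions p_k = N_k / N (sum exactly 1)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty labels")
    return np.bincount(labels) / labels.size


def calinski_harabasz(feature_matrix, labels) -> float:
    """Calinski-Harabasz index [B/(K-1)] / [W/(N-K)] with cluster means.

    Degenerate clusterings with zero within-cluster dispersion (e.g. all
    clusters singletons) return ``inf``.
    """
    X = _as_array(feature_matrix)
    labels = np.asarray(labels, dtype=int)
    ks = np.unique(labels)
    n, k = len(X), len(ks)
    if not 2 <= k <= n - 1:
        raise ValueError(f"need 2 <= K <= N-1, got K={k}, N={n}")
    w = 0.0
    for c in ks:
        pts = X[labels == c]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    if w <= 0.0:
        return float("inf")
    return float(calinski_harabasz_score(X, labels))


def select_k(
    feature_matrix,
    k_min: int = 2,
    k_max: int = 10,
    seed: int | None = None,
    n_restarts: int = 8,
) -> KSelectionReport:
    """Scan K in [k_min, k_max], report inertia + CH, choose K = argmax CH.

    The reported inertia curve is forced non-increasing: if a scan step
    lands on a worse local optimum than K-1, that K is rerun warm-started
    from the K-1 medoids plus the worst-fit point and the better solution
    kept. The elbow (maximum second difference of inertia) is reported
    alongside; CH wins when the two disagree.
    """
    X = _as_array(feature_matrix)
    n = len(X)
    if not 2 <= k_min < k_max <= n - 1:
        raise ValueError(f"need 2 <= k_min < k_max <= N-1 (N={n})")
    ks = list(range(k_min, k_max + 1))
    sols: dict[int, Clustering] = {}
    prev: Clustering | None = None
    for k in ks:
        sol = pam(X, k, seed=seed, n_restarts=n_restarts)
        if prev is not None and sol.inertia > prev.inertia + 1e-9:
            worst = int(np.argmax(
                ((X - X[prev.medoid_indices[prev.labels]]) ** 2).sum(axis=1)
            ))
            warm = list(prev.medoid_indices)
            if worst not in warm:
                warm.append(worst)
            else:  # worst point already a medoid: add farthest non-medoid
                d = ((X - X[prev.medoid_indices[prev.labels]]) ** 2).sum(axis=1)
                d[warm] = -1
                warm.append(int(np.argmax(d)))
            retry = pam(X, k, seed=seed, n_restarts=1, warm_start_medoids=warm[:k])
            if retry.inertia < sol.inertia:
                sol = retry
        sols[k] = sol
        prev = sol
    inertias = [sols[k].inertia for k in ks]
    chs = [calinski_harabasz(X, sols[k].labels) for k in ks]
    chosen = ks[int(np.argmax(chs))]
    elbow = None
    if len(ks) >= 3:
        second_diff = np.diff(inertias, 2)  # at interior K values
        elbow = ks[1 + int(np.argmax(second_diff))]
    return KSelectionReport(
        k_values=ks,
        inertias=inertias,
        ch_scores=chs,
        chosen_k=chosen,
        elbow_k=elbow,
        solutions=sols,
    )
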