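"""Principal component analysis of conformational feature matrices.

PCA here serves visualization only — projecting the trajectory into the
first two principal components to display the cluster partition and its
medoids — never as a preprocessing step for the clustering itself. The
covariance is the population (1/N) covariance of the (already centered,
because standardized) feature matrix; eigenvalues are therefore the
population variances along each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

from medoidspec.cluster import Clustering


@dataclass
class PCAModel:
    """Orthonormal components, descending population-variance eigenvalues."""

    components: np.ndarray  # (d, d) rows = v_j
    eigenvalues: np.ndarray  # (d,) population variances, descending
    mean: np.ndarray  # column means removed before projection

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


class FeaturePCA(TransformerMixin, BaseEstimator):
    """Full-rank PCA with 1/N covariance normalization and fixed signs.

    Wraps :class:`sklearn.decomposition.PCA` (deterministic full SVD) and
    rescales the variances from the sample (1/(N-1)) to the population
    (1/N) convention. Each component's sign is fixed so its
    largest-magnitude entry is positive, making the decomposition unique.

    Attributes: ``components_`` (rows v_j), ``eigenvalues_`` (population
    variances lambda_j, descending), ``explained_fraction_``, ``mean_``.
    """

    def fit(self, X, y=None):
        X = self._as_array(X)
        n = len(X)
        if n < 2:
            raise ValueError("need N >= 2")
        sk = _SkPCA(n_components=min(X.shape), svd_solver="full")
        sk.fit(X)
        comps = sk.components_.copy()
        for j in range(comps.shape[0]):  # deterministic sign convention
            if comps[j, np.argmax(np.abs(comps[j]))] < 0:
                comps[j] = -comps[j]
        self.components_ = comps
        self.eigenvalues_ = sk.explained_variance_ * (n - 1) / n
        self.explained_fraction_ = self.eigenvalues_ / self.eigenvalues_.sum()
        self.mean_ = sk.mean_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, n_components: int | None = None) -> np.ndarray:
        X = self._as_array(X)
        d_r = n_components if n_components is not None else self.components_.shape[0]
        if d_r > self.components_.shape[0]:
            raise ValueError(f"n_components {d_r} > fitted dimension {self.components_.shape[0]}")
        return (X - self.mean_) @ self.components_[:d_r].T

    def model(self) -> PCAModel:
        return PCAModel(
            components=self.components_, eigenvalues=self.eigenvalues_, mean=self.mean_
        )

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.select_dtypes(include=[np.number]).to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input")
        return X


def pca_fit(feature_matrix) -> PCAModel:
    """Fit population-covariance PCA; see :class:`FeaturePCA`."""
    return FeaturePCA().fit(feature_matrix).model()


def project(feature_matrix, model: PCAModel, d_r: int) -> np.ndarray:
    """Project onto the first d_r principal components (N x d_r scores)."""
    X = FeaturePCA._as_array(feature_matrix)
    if d_r > model.components.shape[0]:
        raise ValueError("d_r exceeds the number of components")
    return (X - model.mean) @ model.components[:d_r].T


def cluster_scatter_export(
    scores: np.ndarray,
    clustering: Clustering,
    canonical_labels: bool = True,
) -> pd.DataFrame:
    """Tabulate (PC1, PC2, label, is_medoid) rows for a 2-D cluster map.

    With ``canonical_labels`` the cluster indices are renumbered in
    decreasing cluster-size order (ties by original label), so the output
    is stable under any relabeling permutation of the input clustering.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(clustering.labels):
        raise ValueError("scores and clustering disagree on the number of frames")
    labels = np.asarray(clustering.labels, dtype=int)
    if canonical_labels:
        counts = np.bincount(labels, minlength=clustering.K)
        order = sorted(range(clustering.K), key=lambda c: (-counts[c], c))
        remap = {old: new for new, old in enumerate(order)}
        labels = np.array([remap[l] for l in labels])
    is_medoid = np.zeros(len(labels), dtype=bool)
    is_medoid[np.asarray(clustering.medoid_indices, dtype=int)] = True
    return pd.DataFrame(
        {
            "PC1": scores[:, 0],
            "PC2": scores[:, 1] if scores.shape[1] > 1 else np.zeros(len(labels)),
            "label": labels,
            "is_medoid": is_medoid,
        }
    )


def plot_cluster_scatter(table: pd.DataFrame, path) -> None:
    """Render the exported scatter table to an image file (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, grp in table.groupby("label"):
        ax.scatter(grp["PC1"], grp["PC2"], s=8, label=f"cluster {lab + 1}")
    med = table[table["is_medoid"]]
    ax.scatter(med["PC1"], med["PC2"], marker="*", s=180, c="k", label="medoids")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
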