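"""Euclidean functional trait space (PCA) and functional-group clustering.

Species are placed in a Euclidean space spanned by the principal components
of the standardised trait matrix (all axes kept, so pairwise distances are
preserved exactly), then grouped by agglomerative clustering with Ward
linkage on those scores.  The number of groups k can be fixed (five in the
motivating monitoring study) or chosen by maximum mean silhouette.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score


@dataclasses.dataclass
class FunctionalSpace:
    """PCA representation of the standardised trait matrix."""

    scores: pd.DataFrame        # species x axes
    eigenvalues: np.ndarray     # non-increasing; sums to the trait count
    loadings: pd.DataFrame      # trait x axes
    rank_deficient_axes: list   # axes with (numerically) zero eigenvalue

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


@dataclasses.dataclass
class ClusterAssignment:
    labels: pd.Series           # species_id -> 1..k
    linkage_matrix: np.ndarray
    k: int
    silhouette: float | None
    cluster_means: pd.DataFrame | None = None

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def build_functional_space(matrix: pd.DataFrame) -> FunctionalSpace:
    """Eigendecompose the correlation structure of a standardised matrix.

    All axes are retained.  Sign convention: each axis is flipped so its
    largest-magnitude loading is positive, making output deterministic.
    Axes with eigenvalue ~0 (collinear traits) are retained but flagged.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 species")
    if matrix.isna().any().any():
        raise ValueError("trait matrix contains missing values")
    Z = matrix.to_numpy(dtype=float)
    n = Z.shape[0]
    corr = Z.T @ Z / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for a in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, a]))
        if eigvec[lead, a] < 0:
            eigvec[:, a] *= -1
    axes = [f"PC{i + 1}" for i in range(len(eigval))]
    scores = pd.DataFrame(Z @ eigvec, index=matrix.index, columns=axes)
    loadings = pd.DataFrame(eigvec, index=matrix.columns, columns=axes)
    flagged = [axes[i] for i, ev in enumerate(eigval) if ev < 1e-10]
    return FunctionalSpace(scores=scores, eigenvalues=eigval,
                           loadings=loadings, rank_deficient_axes=flagged)


def _relabel_contiguous(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids to 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_functional_groups(space: FunctionalSpace, k: int | str = 5,
                              traits: pd.DataFrame | None = None,
                              method: str = "ward") -> ClusterAssignment:
    """Agglomerative clustering of species in the full functional space.

    Because every PCA axis is kept, Euclidean distances between scores
    equal distances in the standardised trait space, so this is exactly a
    functional-trait clustering.  ``k="auto"`` picks the k in 2..8 with the
    highest mean silhouette width (ties to the smaller k).
    """
    X = space.scores.to_numpy(dtype=float)
    n = X.shape[0]
    Zlink = linkage(X, method=method)
    if k == "auto":
        best_k, best_s = None, -np.inf
        for kk in range(2, min(8, n - 1) + 1):
            labs = fcluster(Zlink, t=kk, criterion="maxclust")
            if len(np.unique(labs)) < 2:
                continue
            s = silhouette_score(X, labs)
            if s > best_s + 1e-12:
                best_k, best_s = kk, s
        k = best_k
    k = int(k)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of species ({n})")
    raw = fcluster(Zlink, t=k, criterion="maxclust")
    labels = pd.Series(_relabel_contiguous(raw), index=space.scores.index,
                       name="cluster")
    sil = (silhouette_score(X, labels.to_numpy())
           if 1 < k < n else None)
    means = None
    if traits is not None:
        means = traits.loc[labels.index].groupby(labels).mean()
    return ClusterAssignment(labels=labels, linkage_matrix=Zlink, k=k,
                             silhouette=sil, cluster_means=means)
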