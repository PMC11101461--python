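"""Spectral clustering of patient similarity matrices and model selection by
a similarity-space clustering-quality ratio.

The quality ratio Q is a Dunn-index analogue expressed on similarities
rather than distances: the minimum within-cluster pairwise similarity
divided by the maximum between-cluster pairwise similarity.  High Q means
every within-cluster pair is tighter than the loosest between-cluster pair —
homogeneity and separation at once.  The cluster count is chosen by
maximizing Q over a candidate range (default 2..7), ties broken toward the
smaller, more parsimonious count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans


@dataclass
class QualityRatio:
    """Q = (min within-cluster similarity) / (max between-cluster similarity).

    ``degenerate`` flags the Δ=0 case where Q is an infinity/zero sentinel
    rather than a genuine ratio.
    """

    numerator: float
    denominator: float
    Q: float
    degenerate: bool = False


def spectral_cluster(S: np.ndarray, n_clusters: int, seed: int = 0,
                     n_init: int = 50) -> np.ndarray:
    """Normalized-Laplacian spectral clustering (Ng–Jordan–Weiss).

    Embeds patients with the ``n_clusters`` leading eigenvectors of
    D^{-1/2} A D^{-1/2} (diagonal of the similarity zeroed first),
    row-normalizes the embedding and runs seeded k-means with ``n_init``
    restarts.  Deterministic given ``seed``.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not 2 <= n_clusters <= n - 1:
        raise ValueError(f"n_clusters={n_clusters} must lie in [2, {n - 1}]")
    A = S.copy()
    np.fill_diagonal(A, 0.0)
    n_comp, _ = connected_components(A > 0, directed=False)
    if n_comp > n_clusters:
        warnings.warn(
            f"similarity graph has {n_comp} components but {n_clusters} "
            "clusters requested", stacklevel=2)
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    M = inv_sqrt[:, None] * A * inv_sqrt[None, :]
    # top eigenvectors of the normalized affinity = bottom of the Laplacian
    _, vecs = eigh(M, subset_by_index=[n - n_clusters, n - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    emb = np.where(norms > 0, vecs / np.where(norms > 0, norms, 1.0), 0.0)
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    return km.fit_predict(emb)


class SpectralCluster(BaseEstimator, ClusterMixin):
    """Spectral clustering estimator over a precomputed similarity matrix.

    Attributes
    ----------
    labels_ : ndarray of shape (n_patients,)
        Cluster label per patient.
    """

    def __init__(self, n_clusters: int = 4, n_init: int = 50, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, S, y=None):
        self.labels_ = spectral_cluster(
            S, self.n_clusters, seed=self.random_state, n_init=self.n_init)
        return self

    def fit_predict(self, S, y=None):
        return self.fit(S).labels_


def quality_ratio(S: np.ndarray, labels: np.ndarray) -> QualityRatio:
    """Clustering-quality ratio on a similarity matrix.

    ∇(c_k) is the minimum similarity over distinct within-cluster pairs of
    cluster k; the numerator is min_k ∇(c_k); Δ is the maximum similarity
    over all between-cluster pairs; Q = numerator / Δ.  Diagonal entries
    never participate.  Singleton clusters have no within pair and are
    skipped in the numerator's min.  Δ=0 yields an infinity sentinel
    (or 0 when the numerator is also 0), flagged ``degenerate``.
    """
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    n = S.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels do not match similarity matrix")
    uniq = np.unique(labels)
    within_mins = []
    for k in uniq:
        idx = np.flatnonzero(labels == k)
        if idx.size < 2:
            continue  # singleton: no within pair
        block = S[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        within_mins.append(block[iu].min())
    if not within_mins:
        raise ValueError("no within-cluster pair (all clusters singletons)")
    numerator = float(min(within_mins))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    between = S[iu][~same[iu]]
    if between.size == 0:
        raise ValueError("single cluster: no between-cluster pair")
    denominator = float(between.max())
    if denominator > 0:
        return QualityRatio(numerator, denominator, numerator / denominator)
    q = np.inf if numerator > 0 else 0.0
    return QualityRatio(numerator, denominator, q, degenerate=True)


def select_n_clusters(S: np.ndarray, c_range=range(2, 8), seed: int = 0,
                      n_init: int = 50) -> tuple[int, dict[int, float]]:
    """Pick the cluster count maximizing Q over ``c_range``.

    Returns ``(c_star, profile)`` where ``profile`` maps each candidate c to
    its Q value.  Ties break toward smaller c.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    profile: dict[int, float] = {}
    for c in c_range:
        if not 2 <= c <= n - 1:
            raise ValueError(f"candidate c={c} outside [2, {n - 1}]")
        labels = spectral_cluster(S, c, seed=seed, n_init=n_init)
        profile[c] = quality_ratio(S, labels).Q
    best_q = max(profile.values())
    c_star = min(c for c, q in profile.items() if q == best_q)
    return c_star, profile
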