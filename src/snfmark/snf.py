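"""Similarity network fusion: per-layer patient similarity graphs merged by
iterative cross-diffusion.

Each omics layer yields a patient-by-patient affinity matrix from a scaled
exponential kernel whose bandwidth adapts to the local neighbor distances.
Two operators are derived per layer: a *full* kernel P (row-stochastic, half
of each row's mass on the diagonal) carrying the global structure, and a
*sparse* kernel S restricted to each patient's k nearest neighbors, carrying
the locally reliable structure.  Fusion repeatedly pushes each layer's P
through the other layers' average via its own S (P_v ← S_v · mean_{u≠v} P_u
· S_vᵀ), re-symmetrizing and renormalizing every step, and finally averages
the diffused layers.  The relative spectral-norm change between fused graphs
at consecutive hyperparameter settings is the convergence diagnostic used to
pick the iteration count T, neighborhood size k, and kernel scale α
(defaults T=15, k=20, α=0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .datatypes import OmicsMatrix

__all__ = [
    "SnfParams",
    "SNF",
    "affinity",
    "full_kernel",
    "sparse_kernel",
    "fuse",
    "convergence_curve",
]


@dataclass(frozen=True)
class SnfParams:
    """SNF hyperparameters: neighbors k, kernel scale alpha, iterations T."""

    k: int = 20
    alpha: float = 0.5
    T: int = 15

    def validate(self, n_patients: int | None = None) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if n_patients is not None and self.k >= n_patients:
            raise ValueError(f"k={self.k} must be < n_patients={n_patients}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def _as_patient_matrix(data) -> np.ndarray:
    """Accept an OmicsMatrix (features × patients) or array (patients × features)."""
    if isinstance(data, OmicsMatrix):
        return data.values.to_numpy(dtype=float).T
    return np.asarray(data, dtype=float)


def _knn_indices(D: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of each row, self excluded.

    Ties at the k-th neighbor are broken by patient index order (argsort is
    stable on the secondary index), making runs bit-reproducible.
    """
    n = D.shape[0]
    D = D.copy()
    np.fill_diagonal(D, np.inf)  # exclude self
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def affinity(data, params: SnfParams = SnfParams()) -> np.ndarray:
    """Scaled exponential similarity kernel over patients.

    With Euclidean distances d(i,j) and N_i the k nearest neighbors of i,
    the local scale is eps_ij = (mean_{l∈N_i} d(i,l) + mean_{l∈N_j} d(j,l)
    + d(i,j)) / 3 and W(i,j) = exp(-d(i,j)² / (α·eps_ij)).  Duplicate
    patients (d=0) get W=1.
    """
    X = _as_patient_matrix(data)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 patients")
    params.validate(n)
    D = squareform(pdist(X, metric="euclidean"))
    nn = _knn_indices(D, params.k)
    mean_knn = np.take_along_axis(D, nn, axis=1).mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + D) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-(D**2) / (params.alpha * eps))
    # eps == 0 implies d == 0 (eps >= d/3): identical patients, similarity 1
    W[eps == 0] = 1.0
    return (W + W.T) / 2.0


def full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-stochastic full kernel: off-diagonal mass halved, diagonal 1/2.

    P(i,j) = W(i,j) / (2 Σ_{l≠i} W(i,l)) for j≠i and P(i,i) = 1/2, so each
    row sums to one.
    """
    W = np.asarray(W, dtype=float)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsums = off.sum(axis=1)
    if (rowsums <= 0).any():
        raise ValueError("row with no off-diagonal similarity mass")
    P = off / (2.0 * rowsums[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def sparse_kernel(W: np.ndarray, k: int) -> np.ndarray:
    """k-nearest-neighbor kernel: row-normalized over each patient's k
    strongest similarities (self excluded), zero elsewhere.  Generally
    asymmetric.  Neighbor ties are broken by patient index order.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
    neg = -W.copy()
    np.fill_diagonal(neg, np.inf)  # exclude self; sort descending by W
    order = np.argsort(neg, axis=1, kind="stable")[:, :k]
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), k)
    S[rows, order.ravel()] = W[rows, order.ravel()]
    rowsums = S.sum(axis=1)
    if (rowsums <= 0).any():
        raise ValueError("patient with zero similarity to all its neighbors")
    return S / rowsums[:, None]


def _renormalize(P: np.ndarray) -> np.ndarray:
    """Re-symmetrize and restore the half-diagonal row normalization."""
    P = (P + P.T) / 2.0
    return full_kernel(P)


def fuse(W_list: list[np.ndarray], params: SnfParams = SnfParams()) -> np.ndarray:
    """Cross-diffuse ≥2 affinity matrices for T iterations and average.

    All views must share the same patient set and order; no reindexing is
    attempted.  The result is symmetric, nonnegative and row-stochastic with
    half-diagonal.
    """
    if len(W_list) < 2:
        raise ValueError("fusion needs at least two views")
    shapes = {W.shape for W in map(np.asarray, W_list)}
    if len(shapes) != 1:
        raise ValueError(f"views have mismatched shapes: {shapes}")
    n = next(iter(shapes))[0]
    params.validate(n)
    P = [full_kernel(np.asarray(W, dtype=float)) for W in W_list]
    S = [sparse_kernel(np.asarray(W, dtype=float), params.k) for W in W_list]
    V = len(P)
    for _ in range(params.T):
        new = []
        for v in range(V):
            others = sum(P[u] for u in range(V) if u != v) / (V - 1)
            new.append(_renormalize(S[v] @ others @ S[v].T))
        P = new
    fused = sum(P) / V
    return (fused + fused.T) / 2.0


def relative_spectral_change(A: np.ndarray, B: np.ndarray) -> float:
    """‖B − A‖₂ / ‖A‖₂ with the spectral (2-) norm."""
    return float(np.linalg.norm(B - A, 2) / np.linalg.norm(A, 2))


def convergence_curve(W_list: list[np.ndarray], grid, which: str,
                      params: SnfParams = SnfParams()) -> np.ndarray:
    """Relative spectral-norm change of the fused graph along one
    hyperparameter sweep, the other two held fixed.

    ``which`` is one of ``"T"``, ``"k"``, ``"alpha"``.  For ``alpha`` the
    affinities are recomputed per grid value, so ``W_list`` must then be the
    *preprocessed data matrices* (patients × features), not affinities.
    Returns ``len(grid) - 1`` values, one per consecutive grid pair.
    """
    grid = list(grid)
    if len(grid) < 2:
        raise ValueError("grid must contain at least two values")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be sorted ascending")
    if which not in ("T", "k", "alpha"):
        raise ValueError("which must be 'T', 'k' or 'alpha'")

    fused = []
    for g in grid:
        if which == "T":
            p = SnfParams(k=params.k, alpha=params.alpha, T=int(g))
            fused.append(fuse(W_list, p))
        elif which == "k":
            p = SnfParams(k=int(g), alpha=params.alpha, T=params.T)
            fused.append(fuse(W_list, p))
        else:
            p = SnfParams(k=params.k, alpha=float(g), T=params.T)
            W_g = [affinity(X, p) for X in W_list]
            fused.append(fuse(W_g, p))
    return np.array(
        [relative_spectral_change(a, b) for a, b in zip(fused, fused[1:])]
    )


class SNF(BaseEstimator):
    """Similarity-network-fusion estimator over multiple omics views.

    Parameters
    ----------
    k : int
        Nearest-neighbor count for the sparse kernel and the adaptive
        kernel bandwidth.
    alpha : float
        Scale of the exponential similarity kernel.
    n_iter : int
        Number of cross-diffusion iterations T.

    Attributes
    ----------
    fused_similarity_ : ndarray of shape (n_patients, n_patients)
        Symmetric fused similarity matrix.
    affinities_ : list of ndarray
        Per-view affinity matrices.
    """

    def __init__(self, k: int = 20, alpha: float = 0.5, n_iter: int = 15):
        self.k = k
        self.alpha = alpha
        self.n_iter = n_iter

    def _params(self) -> SnfParams:
        return SnfParams(k=self.k, alpha=self.alpha, T=self.n_iter)

    def fit(self, views, y=None):
        """Fit on a list of views (OmicsMatrix or patients×features arrays)."""
        if len(views) < 2:
            raise ValueError("need at least two views")
        mats = [_as_patient_matrix(v) for v in views]
        ns = {m.shape[0] for m in mats}
        if len(ns) != 1:
            raise ValueError("views disagree on the number of patients")
        ids = [tuple(v.patient_ids) for v in views if isinstance(v, OmicsMatrix)]
        if ids and any(i != ids[0] for i in ids[1:]):
            raise ValueError("views disagree on patient ordering")
        p = self._params()
        self.affinities_ = [affinity(m, p) for m in mats]
        self.fused_similarity_ = fuse(self.affinities_, p)
        return self

    def fit_transform(self, views, y=None) -> np.ndarray:
        return self.fit(views).fused_similarity_
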