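"""Ranked-SNF feature scoring and selection.

Each feature is scored by the concordance — normalized mutual information —
between the patient clustering induced by that feature alone (its own
similarity network, spectrally clustered) and the clustering of the fused
multi-omics network.  Features are ranked per layer, the top fraction
(default 10%, ceiling rule) is selected, selected methylation/mRNA features
are mapped to gene symbols, and the genes shared by both layers form the
*essential gene* set carried into the regulatory network.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from . import snf as _snf
from .cluster import spectral_cluster
from .datatypes import OmicsMatrix

__all__ = [
    "nmi",
    "rank_features",
    "top_fraction_count",
    "select_top_fraction",
    "map_features_to_genes",
    "essential_genes",
]


def nmi(a, b) -> float:
    """Normalized mutual information of two partitions, in [0, 1].

    Mutual information normalized by the maximum of the two label entropies;
    symmetric; 1 iff the partitions are identical up to relabeling.  Two
    trivial single-cluster partitions are identical, hence 1; a trivial
    against a non-trivial partition scores 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same patients")
    na, nb = np.unique(a).size, np.unique(b).size
    if na == 1 and nb == 1:
        return 1.0
    if na == 1 or nb == 1:
        return 0.0
    # canonical argument order makes the float result exactly symmetric
    ea = np.unique(a, return_inverse=True)[1]
    eb = np.unique(b, return_inverse=True)[1]
    for x, y in zip(ea, eb):
        if x != y:
            if y < x:
                ea, eb = eb, ea
            break
    return float(normalized_mutual_info_score(ea, eb, average_method="max"))


def rank_features(view: OmicsMatrix, fused_labels: np.ndarray, c: int,
                  params: _snf.SnfParams = _snf.SnfParams(), seed: int = 0,
                  n_init: int = 10) -> pd.DataFrame:
    """Score every feature of one layer against the fused clustering.

    For each feature, a patient similarity matrix is built from that single
    feature's profile (same kernel, k and α as the fused run), spectrally
    clustered into ``c`` groups, and scored by NMI against ``fused_labels``.
    Constant features have a degenerate similarity and score 0.

    Returns a DataFrame sorted by score descending with columns
    ``feature_id``, ``layer``, ``score``, ``rank`` (1 = best); ties broken
    by feature ID for stability.  ``n_init`` k-means restarts per feature
    (fewer than the fused run: thousands of small clusterings).
    """
    fused_labels = np.asarray(fused_labels)
    X = view.values.to_numpy(dtype=float)
    if X.shape[1] != fused_labels.shape[0]:
        raise ValueError("fused labels do not match the view's patients")
    scores = np.empty(X.shape[0])
    for i, row in enumerate(X):
        if np.ptp(row) == 0:  # constant feature: no structure to cluster
            scores[i] = 0.0
            continue
        W = _snf.affinity(row[:, None], params)
        labels = spectral_cluster(W, c, seed=seed, n_init=n_init)
        scores[i] = nmi(labels, fused_labels)
    out = pd.DataFrame({
        "feature_id": view.feature_ids,
        "layer": view.layer,
        "score": np.nan_to_num(scores, nan=0.0),  # degenerate scores rank last
    })
    out = out.sort_values(["score", "feature_id"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_fraction_count(n_features: int, fraction: float = 0.10) -> int:
    """Number of features selected by the top-fraction rule: ⌈fraction·m⌉."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return math.ceil(fraction * n_features)


def select_top_fraction(ranking: pd.DataFrame, fraction: float = 0.10) -> set[str]:
    """Select the top ⌈fraction·m⌉ features of a ranking.

    Boundary ties were already resolved by the stable (score, feature_id)
    ordering in :func:`rank_features`.
    """
    n = top_fraction_count(len(ranking), fraction)
    return set(ranking.nsmallest(n, "rank")["feature_id"])


def map_features_to_genes(features: set[str], annotation: pd.DataFrame) -> set[str]:
    """Union of gene symbols mapped by the selected features.

    ``annotation`` is indexed by reporter/feature ID with a ``genes`` column
    of ";"-separated symbols.  Features absent from the annotation or with
    an empty mapping contribute nothing; one feature may contribute several
    genes.
    """
    genes: set[str] = set()
    present = annotation.index.intersection(list(features))
    for entry in annotation.loc[present, "genes"]:
        if isinstance(entry, str) and entry:
            genes.update(g for g in entry.split(";") if g)
    return genes


def essential_genes(methyl_genes: set[str], mrna_genes: set[str]) -> set[str]:
    """Genes in the top-ranked sets of both the methylation and mRNA layers."""
    shared = methyl_genes & mrna_genes
    if not shared:
        import warnings

        warnings.warn("no shared genes between layers; downstream network "
                      "will be empty", stacklevel=2)
    return shared
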