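"""Quality control and normalization of omics layers.

The filters reproduce the standard hygiene steps for a methylation-array /
RNA-seq / miRNA-seq cohort: a per-sample detection-p screen for the array,
removal of features with missing values, multimapped reporters, sex-chromosome
features (methylation and mRNA only, to avoid sex-linked biomarkers), and
features that are zero in every sample; FPKM→TPM conversion for mRNA; and
per-feature min–max scaling so that every layer feeds the similarity kernel
on a common [0, 1] scale.

Filter order is fixed (NA → multimap → sex → all-zero).  The order affects
the per-step tallies in the :class:`~snfmark.datatypes.FilterReport` but not
the surviving feature set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import SEX_CHROMOSOMES, FilterReport, OmicsMatrix

#: strict upper bound on the per-sample mean detection p-value
DETECTION_P_THRESHOLD = 0.005


def qc_detection(matrix: OmicsMatrix, detection_p: pd.Series,
                 threshold: float = DETECTION_P_THRESHOLD) -> pd.Series:
    """Per-sample detection-p screen for the methylation array.

    A sample passes iff its mean detection p-value is strictly below
    ``threshold``.  Returns a boolean Series indexed by patient ID.
    """
    if matrix.layer != "methylation":
        raise ValueError("detection-p screening applies to the methylation layer only")
    detection_p = detection_p.reindex(matrix.patient_ids)
    if detection_p.isna().any():
        missing = list(detection_p.index[detection_p.isna()])
        raise ValueError(f"missing detection p-values for samples: {missing}")
    arr = detection_p.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("detection p-values must lie in [0, 1]")
    return pd.Series(arr < threshold, index=matrix.patient_ids, name="detection_pass")


def filter_features(matrix: OmicsMatrix) -> tuple[OmicsMatrix, FilterReport]:
    """Remove defective features in the fixed order NA → multimap → sex → zero.

    The sex-chromosome filter applies to the methylation and mRNA layers only;
    miRNA features are retained regardless of chromosome.  Raises if no
    feature survives (over-filtering is always a data problem).
    """
    report = FilterReport(layer=matrix.layer, n_before=matrix.n_features)
    values = matrix.values
    meta = matrix.feature_meta

    keep = pd.Series(True, index=values.index)

    na_rows = values.isna().any(axis=1)
    report.removed["na"] = int((keep & na_rows).sum())
    keep &= ~na_rows

    if meta is not None and "multimapped" in meta.columns:
        multi = meta["multimapped"].astype(bool)
    else:
        multi = pd.Series(False, index=values.index)
    report.removed["multimapped"] = int((keep & multi).sum())
    keep &= ~multi

    if matrix.layer in ("methylation", "mrna") and meta is not None and "chromosome" in meta.columns:
        sex = meta["chromosome"].isin(SEX_CHROMOSOMES)
    else:
        sex = pd.Series(False, index=values.index)
    report.removed["sex_chromosome"] = int((keep & sex).sum())
    keep &= ~sex

    all_zero = values.fillna(np.inf).eq(0).all(axis=1)  # NA rows already gone
    report.removed["all_zero"] = int((keep & all_zero).sum())
    keep &= ~all_zero

    out = matrix.subset_features(values.index[keep])
    report.n_after = out.n_features
    report.validate()
    if out.n_features == 0:
        raise ValueError(f"all {matrix.layer} features removed by filtering")
    return out, report


def fpkm_to_tpm(matrix: OmicsMatrix) -> OmicsMatrix:
    """Rescale each patient column of an mRNA FPKM matrix to TPM.

    TPM_ij = FPKM_ij / sum_i FPKM_ij * 1e6, so every column sums to 1e6.
    Within-column rank order is preserved.
    """
    if matrix.layer != "mrna":
        raise ValueError("FPKM→TPM conversion applies to the mRNA layer only")
    vals = matrix.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    colsums = vals.sum(axis=0)
    if (colsums <= 0).any():
        bad = list(colsums.index[colsums <= 0])
        raise ValueError(f"patient columns with zero total FPKM: {bad}")
    out = matrix.copy()
    out.values = vals.div(colsums, axis=1) * 1e6
    return out


def minmax_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Rescale each feature row to [0, 1] via (x - min) / (max - min).

    Constant rows map to all-zeros (kept, not dropped, so the feature
    accounting of the filter report stays valid downstream).
    """
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("normalize after removing NA features")
    arr = vals.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (arr - lo) / span, 0.0)
    out = matrix.copy()
    out.values = pd.DataFrame(scaled, index=vals.index, columns=vals.columns)
    return out


def preprocess_layer(matrix: OmicsMatrix) -> tuple[OmicsMatrix, FilterReport]:
    """Full per-layer pipeline: filter, convert units (mRNA), min–max scale."""
    filtered, report = filter_features(matrix)
    if filtered.layer == "mrna":
        filtered = fpkm_to_tpm(filtered)
    return minmax_normalize(filtered), report
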