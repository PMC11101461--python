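"""Shared in-memory containers for omics matrices and filter accounting.

An :class:`OmicsMatrix` is the unit every pipeline stage consumes: a
feature-by-patient table of one molecular layer together with per-feature
annotation (chromosome, mapped gene symbols, multimapping flag).  Missing
measurements are carried as ``NaN`` in ``values``; no separate mask is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("methylation", "mrna", "mirna")

#: chromosome labels treated as sex chromosomes by the feature filters
SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class OmicsMatrix:
    """One omics layer as a feature-by-patient matrix plus feature metadata.

    Parameters
    ----------
    layer
        One of ``"methylation"`` (beta values in [0, 1]), ``"mrna"``
        (FPKM/TPM) or ``"mirna"`` (expression counts or RPM).
    values
        DataFrame indexed by feature ID with one column per patient ID.
    feature_meta
        DataFrame indexed identically to ``values`` with columns
        ``chromosome`` (str), ``genes`` (";"-separated symbols, possibly
        empty) and ``multimapped`` (bool).  May be ``None`` for layers
        without annotation (miRNA).
    """

    layer: str
    values: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate patient IDs")
        if self.feature_meta is not None and not self.feature_meta.index.equals(
            self.values.index
        ):
            raise ValueError("feature_meta index does not match values index")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            layer=self.layer,
            values=self.values.copy(),
            feature_meta=None if self.feature_meta is None else self.feature_meta.copy(),
        )

    def subset_features(self, keep: pd.Index | np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(
            layer=self.layer,
            values=self.values.loc[keep],
            feature_meta=None if self.feature_meta is None else self.feature_meta.loc[keep],
        )

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, layer: str, feature_meta: pd.DataFrame | None = None
                 ) -> "OmicsMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(layer=layer, values=values, feature_meta=feature_meta)


@dataclass
class FilterReport:
    """Per-step accounting of feature removal for one layer.

    ``removed`` preserves filter order; the invariant
    ``n_before - sum(removed.values()) == n_after`` is enforced.
    """

    layer: str
    n_before: int
    removed: dict[str, int] = field(default_factory=dict)
    n_after: int = 0

    def validate(self) -> None:
        if self.n_before - sum(self.removed.values()) != self.n_after:
            raise ValueError(
                f"filter report does not reconcile: {self.n_before} - "
                f"{sum(self.removed.values())} != {self.n_after}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "layer": self.layer,
                "n_before": self.n_before,
                "removed": self.removed,
                "n_after": self.n_after,
            },
            indent=2,
        )

    def log_lines(self) -> list[str]:
        lines = [f"[{self.layer}] features before filtering: {self.n_before}"]
        for step, n in self.removed.items():
            lines.append(f"[{self.layer}]   removed by {step}: {n}")
        lines.append(f"[{self.layer}] features after filtering: {self.n_after}")
        return lines


def read_annotation(path) -> pd.DataFrame:
    """Read a reporter annotation table (reporter_id, gene_symbol, chromosome)."""
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return ann.set_index("reporter_id")


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.index.name = "reporter_id"
    out.to_csv(path, sep="\t")
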