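"""End-to-end orchestration: cohort → preprocessing → fusion → clustering →
feature ranking → regulatory network → biomarker validation.

The pipeline runs either on a synthetic cohort described by a
:class:`~snfmark.synthetic.CohortSpec` or on user-supplied TSV tables laid
out as written by :func:`~snfmark.synthetic.write_cohort`.  Every stage
writes its artifact under the output directory and contributes to a single
machine-readable ``summary.json``; any stage failure aborts with a
stage-tagged error, retaining partial outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import rank as _rank
from . import regnet as _regnet
from . import snf as _snf
from . import validate as _validate
from .datatypes import OmicsMatrix, read_annotation
from .preprocess import preprocess_layer, qc_detection
from .synthetic import (CohortSpec, MultiOmicsCohort, generate_cohort,
                        generate_interaction_tables, read_interactions,
                        write_cohort, write_interactions)

log = logging.getLogger("snfmark")

LAYER_ORDER = ("methylation", "mrna", "mirna")


@dataclass
class PipelineConfig:
    """Configuration mirroring the study defaults.

    ``data_dir`` switches from synthetic generation to reading TSV inputs.
    """

    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    data_dir: str | None = None
    snf_params: _snf.SnfParams = field(default_factory=_snf.SnfParams)
    c_range: tuple[int, int] = (2, 7)
    top_fraction: float = 0.10
    n_hubs: int = 10
    dichotomize_delta: float = 0.25
    dichotomize_mid: str = "exclude"
    convergence_t_max: int = 20
    seed: int = 0
    outdir: str = "snfmark_output"

    def validate(self) -> None:
        if self.data_dir is None:
            self.cohort_spec.validate()
        self.snf_params.validate()
        lo, hi = self.c_range
        if not 2 <= lo <= hi:
            raise ValueError("invalid cluster range")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.n_hubs < 1 or self.dichotomize_delta < 0:
            raise ValueError("n_hubs >= 1 and dichotomize_delta >= 0 required")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; message carries the stage tag."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - retag with stage name
                raise StageError(f"[{name}] {err}") from err
        return wrapped
    return deco


def load_cohort(data_dir) -> MultiOmicsCohort:
    """Read a cohort from TSV tables laid out as by ``write_cohort``."""
    d = Path(data_dir)
    ann = read_annotation(d / "annotation.tsv")
    if "multimapped" in ann.columns:
        ann["multimapped"] = ann["multimapped"].astype(str).str.lower() == "true"
    layers = {}
    for name in LAYER_ORDER:
        values = pd.read_csv(d / f"{name}.tsv", sep="\t", index_col=0)
        meta = ann.reindex(values.index)
        if name == "mirna":
            meta = None
        else:
            meta = meta.fillna({"genes": "", "chromosome": "", "multimapped": False})
        layers[name] = OmicsMatrix(name, values, meta)
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t", index_col=0)
    dp_path = d / "detection_p.tsv"
    if dp_path.exists():
        detection_p = pd.read_csv(dp_path, sep="\t", index_col=0).iloc[:, 0]
    else:
        detection_p = pd.Series(0.0, index=layers["methylation"].patient_ids)
    sub_path = d / "true_subtype.tsv"
    if sub_path.exists():
        true_subtype = pd.read_csv(sub_path, sep="\t", index_col=0).iloc[:, 0]
    else:
        true_subtype = pd.Series(-1, index=layers["methylation"].patient_ids)
    return MultiOmicsCohort(layers=layers, true_subtype=true_subtype,
                            clinical=clinical, annotation=ann,
                            detection_p=detection_p, truth={})


@_stage("preprocess")
def _preprocess(cohort: MultiOmicsCohort, outdir: Path):
    passed = qc_detection(cohort.layers["methylation"], cohort.detection_p)
    if not passed.all():
        failed = list(passed.index[~passed])
        log.warning("dropping %d samples failing detection QC: %s",
                    len(failed), failed)
    keep = list(passed.index[passed])
    processed, reports = {}, {}
    for name in LAYER_ORDER:
        layer = cohort.layers[name]
        layer = OmicsMatrix(name, layer.values[keep], layer.feature_meta)
        processed[name], reports[name] = preprocess_layer(layer)
    (outdir / "filter_report.json").write_text(json.dumps(
        {n: json.loads(r.to_json()) for n, r in reports.items()}, indent=2))
    with open(outdir / "filter_report.txt", "w") as fh:
        for r in reports.values():
            fh.write("\n".join(r.log_lines()) + "\n")
    for name, layer in processed.items():
        layer.to_tsv(outdir / f"{name}_processed.tsv")
    return processed, reports


@_stage("fuse")
def _fuse(processed, config: PipelineConfig, outdir: Path):
    model = _snf.SNF(k=config.snf_params.k, alpha=config.snf_params.alpha,
                     n_iter=config.snf_params.T)
    fused = model.fit_transform([processed[n] for n in LAYER_ORDER])
    patients = processed["mrna"].patient_ids
    pd.DataFrame(fused, index=patients, columns=patients).to_csv(
        outdir / "fused_similarity.tsv", sep="\t")
    t_grid = list(range(2, config.convergence_t_max + 1))
    curve = _snf.convergence_curve(model.affinities_, t_grid, "T",
                                   config.snf_params)
    (outdir / "convergence.json").write_text(json.dumps(
        {"which": "T", "grid": t_grid, "relative_change": list(curve)}, indent=2))
    return fused, curve


@_stage("cluster")
def _cluster_stage(fused, config: PipelineConfig, outdir: Path, patients):
    lo, hi = config.c_range
    c_star, profile = _cluster.select_n_clusters(
        fused, range(lo, hi + 1), seed=config.seed)
    labels = _cluster.spectral_cluster(fused, c_star, seed=config.seed)
    pd.DataFrame({"patient_id": patients, "cluster": labels}).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)
    (outdir / "q_profile.json").write_text(json.dumps(
        {"c_star": c_star, "profile": {str(c): q for c, q in profile.items()}},
        indent=2))
    return c_star, profile, labels


@_stage("rank")
def _rank_stage(processed, labels, c_star, cohort, config: PipelineConfig,
                outdir: Path):
    rankings, selected = {}, {}
    for name in LAYER_ORDER:
        r = _rank.rank_features(processed[name], labels, c_star,
                                params=config.snf_params, seed=config.seed)
        r.to_csv(outdir / f"ranking_{name}.tsv", sep="\t", index=False)
        rankings[name] = r
        selected[name] = _rank.select_top_fraction(r, config.top_fraction)
    meth_genes = _rank.map_features_to_genes(selected["methylation"],
                                             cohort.annotation)
    mrna_genes = _rank.map_features_to_genes(selected["mrna"], cohort.annotation)
    essential = _rank.essential_genes(meth_genes, mrna_genes)
    (outdir / "essential_genes.txt").write_text(
        "\n".join(sorted(essential)) + "\n")
    (outdir / "highrank_mirnas.txt").write_text(
        "\n".join(sorted(selected["mirna"])) + "\n")
    return rankings, selected, meth_genes, mrna_genes, essential


@_stage("network")
def _network_stage(records, highrank_mirnas, essential, config, outdir: Path):
    kept = _regnet.filter_interactions(records, highrank_mirnas, essential)
    net = _regnet.build_network(kept)
    scores = _regnet.mcc_scores(net)
    hubs = _regnet.top_hubs(scores, config.n_hubs)
    _regnet.write_sif(net, outdir / "network.sif")
    _regnet.write_graphml(net, outdir / "network.graphml")
    _regnet.write_hub_table(hubs, outdir / "hubs.tsv")
    return kept, net, scores, hubs


def _expression_for(node: str, role: str, processed, annotation) -> pd.Series | None:
    """Expression profile of a hub node from the processed layers."""
    if role == "miRNA":
        layer = processed["mirna"]
        if node in layer.feature_ids:
            return layer.values.loc[node]
        return None
    layer = processed["mrna"]
    meta = layer.feature_meta
    hits = meta.index[meta["genes"].astype(str).str.split(";")
                      .apply(lambda gs: node in gs)]
    if len(hits) == 0:
        return None
    return layer.values.loc[hits[0]]


@_stage("validate")
def _validate_stage(hubs, processed, cohort, config: PipelineConfig,
                    outdir: Path):
    rows = []
    stage4 = (cohort.clinical["inss_stage"].astype(str) == "4").astype(int)
    for hub in hubs:
        expr = _expression_for(hub.node, hub.role, processed, cohort.annotation)
        if expr is None:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                panel = _validate.survival_validation(
                    expr, cohort.clinical, delta=config.dichotomize_delta,
                    mid=config.dichotomize_mid)
            except ValueError:  # e.g. constant expression row
                continue
            try:
                auc, _ = _validate.roc_auc(
                    expr.to_numpy(), stage4.reindex(expr.index).to_numpy())
            except ValueError:  # a single stage class in a tiny cohort
                auc = None
        row = {"node": hub.node, "role": hub.role, "mcc": hub.mcc,
               "stage4_auc": auc}
        row.update(panel)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    return table


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the summary dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.data_dir is not None:
        cohort = load_cohort(config.data_dir)
        records = read_interactions(Path(config.data_dir) / "tf_mirna.tsv",
                                    Path(config.data_dir) / "mirna_target.tsv")
    else:
        cohort = generate_cohort(config.cohort_spec)
        tables = generate_interaction_tables(cohort, config.cohort_spec)
        records = tables.records
        raw = outdir / "raw"
        write_cohort(cohort, raw)
        write_interactions(tables, raw)

    processed, reports = _preprocess(cohort, outdir)
    fused, curve = _fuse(processed, config, outdir)
    patients = processed["mrna"].patient_ids
    c_star, profile, labels = _cluster_stage(fused, config, outdir, patients)
    rankings, selected, meth_genes, mrna_genes, essential = _rank_stage(
        processed, labels, c_star, cohort, config, outdir)
    kept, net, scores, hubs = _network_stage(
        records, selected["mirna"], essential, config, outdir)
    validation = _validate_stage(hubs, processed, cohort, config, outdir)

    summary: dict = {
        "n_patients": int(len(patients)),
        "filter_report": {n: json.loads(r.to_json()) for n, r in reports.items()},
        "snf": {"k": config.snf_params.k, "alpha": config.snf_params.alpha,
                "T": config.snf_params.T},
        "convergence_final_change": float(curve[-1]),
        "c_star": int(c_star),
        "q_profile": {str(c): float(q) for c, q in profile.items()},
        "n_selected": {n: len(selected[n]) for n in LAYER_ORDER},
        "n_methylation_genes": len(meth_genes),
        "n_mrna_genes": len(mrna_genes),
        "n_essential_genes": len(essential),
        "network": {"n_nodes": int(net.number_of_nodes()),
                    "n_edges": int(net.number_of_edges()),
                    "n_records_kept": int(len(kept))},
        "top_hubs": [h.__dict__ for h in hubs],
        "validation": validation.to_dict(orient="records"),
    }
    if (cohort.true_subtype >= 0).all():
        summary["subtype_recovery_nmi"] = float(
            _rank.nmi(labels, cohort.true_subtype.loc[patients].to_numpy()))
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True))
    return summary
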