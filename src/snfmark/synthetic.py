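"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the statistical structure of a pediatric-tumor multi-omics cohort:
~99 patients carrying ~4 latent molecular subtypes observed through three
layers (methylation beta values, mRNA FPKM, miRNA expression), where only a
minority of features per layer are subtype-informative; defective features
(missing values, multimapped reporters, sex-chromosome probes, all-zero
rows) are injected at configurable rates; survival follows an exponential
proportional-hazards model with per-subtype hazard ratios and uniform
administrative censoring; tumor stage is drawn from per-subtype
distributions.  Interaction tables in the vocabulary of curated TF–miRNA
and miRNA–target databases (sign, evidence level, cell-line context) are
generated with a planted hub TF and hub miRNA of maximal connectivity.

Everything is reproducible bit-for-bit from the spec seed.  Defects are
injected into non-informative features only, so the planted truth survives
preprocessing and recovery rates are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import OmicsMatrix, write_annotation

INSS_STAGES = ("1", "2", "3", "4", "4S")

#: baseline hazard: median survival of 1500 days at hazard ratio 1
BASELINE_HAZARD = np.log(2) / 1500.0

# stage mixes for the least and most aggressive subtype; intermediate
# subtypes interpolate by hazard-ratio rank
_STAGE_BENIGN = np.array([0.40, 0.30, 0.10, 0.05, 0.15])
_STAGE_AGGRESSIVE = np.array([0.05, 0.10, 0.25, 0.55, 0.05])


@dataclass
class CohortSpec:
    """Ground-truth parameters of a synthetic multi-omics cohort."""

    n_patients: int = 99
    n_subtypes: int = 4
    subtype_proportions: tuple[float, ...] | None = None  # None = equal
    n_methylation: int = 2000
    n_mrna: int = 2000
    n_mirna: int = 2000
    informative_fraction: float = 0.10
    effect_size: float = 3.0  # mean shift between subtypes, in noise-SD units
    noise_sd: float = 1.0
    frac_na: float = 0.20  # methylation only
    frac_multimapped: float = 0.02  # methylation only
    frac_sex_chrom: float = 0.03  # methylation and mRNA
    frac_all_zero: float = 0.02  # all layers
    subtype_hazard_ratios: tuple[float, ...] | None = None
    censoring_rate: float = 0.30
    stage_distributions: np.ndarray | None = None  # n_subtypes × 5
    n_planted_hubs: int = 1
    hub_out_degree: int = 12
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.subtype_proportions is None:
            return np.full(self.n_subtypes, 1.0 / self.n_subtypes)
        return np.asarray(self.subtype_proportions, dtype=float)

    def hazard_ratios(self) -> np.ndarray:
        if self.subtype_hazard_ratios is None:
            # geometric spread around 1 so subtypes separate in survival
            return np.geomspace(0.4, 6.0, self.n_subtypes)
        return np.asarray(self.subtype_hazard_ratios, dtype=float)

    def stage_matrix(self) -> np.ndarray:
        if self.stage_distributions is not None:
            M = np.asarray(self.stage_distributions, dtype=float)
        else:
            ranks = np.argsort(np.argsort(self.hazard_ratios()))
            w = ranks / max(self.n_subtypes - 1, 1)
            M = (1 - w[:, None]) * _STAGE_BENIGN + w[:, None] * _STAGE_AGGRESSIVE
        if M.shape != (self.n_subtypes, len(INSS_STAGES)):
            raise ValueError("stage_distributions must be n_subtypes x 5")
        if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("stage distributions must each sum to 1")
        return M

    def validate(self) -> None:
        if min(self.n_patients, self.n_subtypes, self.n_methylation,
               self.n_mrna, self.n_mirna) <= 0:
            raise ValueError("counts must be positive")
        if self.n_subtypes > self.n_patients:
            raise ValueError("more subtypes than patients")
        p = self.proportions()
        if len(p) != self.n_subtypes:
            raise ValueError("proportions length must equal n_subtypes")
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("subtype proportions must be nonnegative and sum to 1")
        for name in ("informative_fraction", "frac_na", "frac_multimapped",
                     "frac_sex_chrom", "frac_all_zero", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        hr = self.hazard_ratios()
        if len(hr) != self.n_subtypes or (hr <= 0).any():
            raise ValueError("need one positive hazard ratio per subtype")
        self.stage_matrix()


@dataclass
class MultiOmicsCohort:
    """Generated cohort: three layers, clinical data, annotation, truth."""

    layers: dict[str, OmicsMatrix]
    true_subtype: pd.Series
    clinical: pd.DataFrame
    annotation: pd.DataFrame
    detection_p: pd.Series
    truth: dict = field(default_factory=dict)

    @property
    def patient_ids(self) -> pd.Index:
        return self.true_subtype.index


@dataclass
class InteractionTables:
    """TF→miRNA and miRNA→target records plus the planted-hub bookkeeping."""

    records: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def tf_mirna(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "tf_mirna"].reset_index(drop=True)

    @property
    def mirna_target(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "mirna_target"].reset_index(drop=True)


def _subtype_labels(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder subtype counts, order shuffled."""
    p = spec.proportions()
    base = np.floor(p * spec.n_patients).astype(int)
    short = spec.n_patients - base.sum()
    remainder_order = np.argsort(-(p * spec.n_patients - base), kind="stable")
    base[remainder_order[:short]] += 1
    labels = np.repeat(np.arange(spec.n_subtypes), base)
    rng.shuffle(labels)
    return labels


def _binary_patterns(n_features: int, n_subtypes: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-feature binary subtype patterns, guaranteed non-constant."""
    pat = rng.integers(0, 2, size=(n_features, n_subtypes))
    for i in np.flatnonzero(pat.min(axis=1) == pat.max(axis=1)):
        pat[i, rng.integers(n_subtypes)] ^= 1
    return pat


def _draw_layer(n_features: int, spec: CohortSpec, labels: np.ndarray,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent Gaussian feature-by-patient matrix with planted signal.

    Returns (matrix, informative_index).  Informative features shift their
    mean by effect_size·noise_sd for a random, non-constant subset of
    subtypes.
    """
    n_inf = int(round(spec.informative_fraction * n_features))
    informative = np.sort(rng.choice(n_features, size=n_inf, replace=False))
    base = rng.normal(0.0, 1.0, size=n_features)
    X = base[:, None] + rng.normal(0.0, spec.noise_sd,
                                   size=(n_features, spec.n_patients))
    if n_inf:
        pat = _binary_patterns(n_inf, spec.n_subtypes, rng)
        shift = spec.effect_size * spec.noise_sd
        X[informative] += shift * pat[:, labels]
    return X, informative


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _disjoint_draws(pool: np.ndarray, sizes: list[int],
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Sample disjoint subsets of the given sizes from a pool."""
    if sum(sizes) > pool.size:
        raise ValueError("defect fractions exceed the non-informative pool")
    picked = rng.choice(pool, size=sum(sizes), replace=False)
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(picked[start:start + s]))
        start += s
    return out


def _expected_censoring(c_max: float, rates: np.ndarray, probs: np.ndarray) -> float:
    """P(censored) under U(0, c_max) censoring of an exponential mixture."""
    return float(np.sum(probs * (1 - np.exp(-rates * c_max)) / (rates * c_max)))


def generate_cohort(spec: CohortSpec) -> MultiOmicsCohort:
    """Generate the full multi-omics cohort described by ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    patients = pd.Index([f"P{i + 1:03d}" for i in range(spec.n_patients)],
                        name="patient_id")
    labels = _subtype_labels(spec, rng)

    genes = np.array([f"GENE{i + 1:05d}" for i in range(spec.n_mrna)])
    autosomes = np.array([f"chr{i}" for i in range(1, 23)])

    # ---- mRNA layer: log-normal FPKM, one gene per transcript feature ----
    mrna_ids = pd.Index([f"TX{i + 1:05d}" for i in range(spec.n_mrna)])
    latent, inf_mrna = _draw_layer(spec.n_mrna, spec, labels, rng)
    fpkm = np.exp(latent + 2.0)  # location keeps FPKM in a plausible range
    informative_genes = [str(g) for g in genes[inf_mrna]]
    mrna_chrom = rng.choice(autosomes, size=spec.n_mrna)

    # ---- methylation layer: sigmoid-squashed Gaussian beta values ----
    meth_ids = pd.Index([f"cg{i + 1:08d}" for i in range(spec.n_methylation)])
    latent_m, inf_meth = _draw_layer(spec.n_methylation, spec, labels, rng)
    beta = _sigmoid(latent_m)
    # informative reporters map onto the informative genes (round-robin) so
    # that true signal genes are discoverable from both layers
    meth_genes = np.array([""] * spec.n_methylation, dtype=object)
    if informative_genes:
        for j, fi in enumerate(inf_meth):
            meth_genes[fi] = informative_genes[j % len(informative_genes)]
    background = np.setdiff1d(np.arange(spec.n_methylation), inf_meth)
    mapped = rng.random(background.size) < 0.8
    meth_genes[background[mapped]] = rng.choice(genes, size=int(mapped.sum()))
    # a sprinkle of two-gene reporters exercises multi-gene mapping
    two = background[mapped][rng.random(int(mapped.sum())) < 0.05]
    for fi in two:
        meth_genes[fi] = meth_genes[fi] + ";" + rng.choice(genes)
    meth_chrom = rng.choice(autosomes, size=spec.n_methylation)
    meth_multi = np.zeros(spec.n_methylation, dtype=bool)

    # ---- miRNA layer: log-normal expression ----
    mirna_ids = pd.Index([f"hsa-mir-{i + 1:04d}" for i in range(spec.n_mirna)])
    latent_mi, inf_mirna = _draw_layer(spec.n_mirna, spec, labels, rng)
    mirna_expr = np.exp(latent_mi + 1.0)
    mirna_chrom = rng.choice(np.r_[autosomes, ["chrX"]], size=spec.n_mirna)

    # ---- defect injection (non-informative features only) ----
    n_na = int(round(spec.frac_na * spec.n_methylation))
    n_multi = int(round(spec.frac_multimapped * spec.n_methylation))
    n_sex_m = int(round(spec.frac_sex_chrom * spec.n_methylation))
    n_zero_m = int(round(spec.frac_all_zero * spec.n_methylation))
    na_idx, multi_idx, sex_idx, zero_idx = _disjoint_draws(
        background, [n_na, n_multi, n_sex_m, n_zero_m], rng)
    for fi in na_idx:
        k = max(1, rng.binomial(spec.n_patients, 0.3))
        cols = rng.choice(spec.n_patients, size=k, replace=False)
        beta[fi, cols] = np.nan
    meth_multi[multi_idx] = True
    meth_chrom[sex_idx] = rng.choice(["chrX", "chrY"], size=sex_idx.size)
    beta[zero_idx] = 0.0

    bg_mrna = np.setdiff1d(np.arange(spec.n_mrna), inf_mrna)
    n_sex_r = int(round(spec.frac_sex_chrom * spec.n_mrna))
    n_zero_r = int(round(spec.frac_all_zero * spec.n_mrna))
    sex_r, zero_r = _disjoint_draws(bg_mrna, [n_sex_r, n_zero_r], rng)
    mrna_chrom[sex_r] = rng.choice(["chrX", "chrY"], size=sex_r.size)
    fpkm[zero_r] = 0.0

    bg_mirna = np.setdiff1d(np.arange(spec.n_mirna), inf_mirna)
    n_zero_mi = int(round(spec.frac_all_zero * spec.n_mirna))
    (zero_mi,) = _disjoint_draws(bg_mirna, [n_zero_mi], rng)
    mirna_expr[zero_mi] = 0.0

    # ---- containers ----
    def _meta(ids, chrom, gene_list, multi):
        return pd.DataFrame(
            {"chromosome": chrom, "genes": gene_list, "multimapped": multi},
            index=ids)

    layers = {
        "methylation": OmicsMatrix(
            "methylation", pd.DataFrame(beta, index=meth_ids, columns=patients),
            _meta(meth_ids, meth_chrom, meth_genes, meth_multi)),
        "mrna": OmicsMatrix(
            "mrna", pd.DataFrame(fpkm, index=mrna_ids, columns=patients),
            _meta(mrna_ids, mrna_chrom, genes, np.zeros(spec.n_mrna, bool))),
        "mirna": OmicsMatrix(
            "mirna", pd.DataFrame(mirna_expr, index=mirna_ids, columns=patients),
            _meta(mirna_ids, mirna_chrom, [""] * spec.n_mirna,
                  np.zeros(spec.n_mirna, bool))),
    }

    annotation = pd.concat([
        layers["methylation"].feature_meta[["genes", "chromosome", "multimapped"]],
        layers["mrna"].feature_meta[["genes", "chromosome", "multimapped"]],
    ])
    annotation.index.name = "reporter_id"

    # ---- clinical table ----
    hr = spec.hazard_ratios()
    rates = BASELINE_HAZARD * hr[labels]
    t_event = rng.exponential(1.0 / rates)
    if spec.censoring_rate > 0:
        probs = spec.proportions()
        all_rates = BASELINE_HAZARD * hr
        c_max = brentq(
            lambda c: _expected_censoring(c, all_rates, probs) - spec.censoring_rate,
            1e-3, 1e9)
        c_time = rng.uniform(0.0, c_max, size=spec.n_patients)
        os_time = np.minimum(t_event, c_time)
        os_event = (t_event <= c_time).astype(int)
    else:
        os_time, os_event = t_event, np.ones(spec.n_patients, dtype=int)
    os_time = np.maximum(os_time, 0.5)  # keep times strictly positive

    stage_matrix = spec.stage_matrix()
    stages = np.array([
        INSS_STAGES[rng.choice(len(INSS_STAGES), p=stage_matrix[s])]
        for s in labels
    ])
    clinical = pd.DataFrame({
        "os_time_days": os_time,
        "os_event": os_event,
        "inss_stage": stages,
    }, index=patients)

    detection_p = pd.Series(rng.uniform(5e-4, 3e-3, size=spec.n_patients),
                            index=patients, name="mean_detection_p")

    truth = {
        "methylation": list(meth_ids[inf_meth]),
        "mrna": list(mrna_ids[inf_mrna]),
        "mirna": list(mirna_ids[inf_mirna]),
        "informative_genes": informative_genes,
    }
    return MultiOmicsCohort(
        layers=layers,
        true_subtype=pd.Series(labels, index=patients, name="true_subtype"),
        clinical=clinical,
        annotation=annotation,
        detection_p=detection_p,
        truth=truth,
    )


def generate_interaction_tables(cohort: MultiOmicsCohort,
                                spec: CohortSpec) -> InteractionTables:
    """Interaction tables with a planted hub TF and hub miRNA.

    The hub TF regulates ``spec.hub_out_degree`` high-rank miRNAs; the hub
    miRNA targets several essential genes and is regulated by two further
    TFs.  Background edges are degree-capped below the hub degree, and decoy
    records (evidence ``other``, normal cell-line context, endpoints outside
    the selected sets) exercise every downstream filter branch.
    """
    rng = np.random.default_rng(spec.seed + 1)
    inf_genes = list(cohort.truth["informative_genes"])
    inf_mirnas = list(cohort.truth["mirna"])
    if len(inf_genes) < 10 or len(inf_mirnas) < 10:
        raise ValueError("too few informative genes/miRNAs for interaction tables")
    # hub out-degree bounded by the available high-rank miRNAs
    out_degree = min(spec.hub_out_degree, len(inf_mirnas))

    rows: list[dict] = []

    def add(src, dst, kind, sign, evidence="literature", context="tumor"):
        rows.append({"source": src, "target": dst, "kind": kind, "sign": sign,
                     "evidence": evidence, "context": context})

    degree: dict[str, int] = {}

    def bump(*nodes):
        for v in nodes:
            degree[v] = degree.get(v, 0) + 1

    truth: dict = {}
    cap = max(2, out_degree - 4)

    if spec.n_planted_hubs > 0:
        hub_tf, hub_mirna = inf_genes[0], inf_mirnas[0]
        truth = {"hub_tf": hub_tf, "hub_mirna": hub_mirna}
        hub_mirs = inf_mirnas[:out_degree]
        for j, m in enumerate(hub_mirs):
            add(hub_tf, m, "tf_mirna", "activation",
                evidence="level2" if j % 2 else "literature")
            bump(hub_tf, m)
        for g in inf_genes[1:7]:
            add(hub_mirna, g, "mirna_target", "repression")
            bump(hub_mirna, g)
        for tf in inf_genes[7:9]:
            add(tf, hub_mirna, "tf_mirna", "regulation")
            bump(tf, hub_mirna)
        protected = {hub_tf}
    else:
        protected = set()

    tf_pool = inf_genes[1:21]
    target_pool = inf_genes[1:]
    mir_pool = inf_mirnas[1:] if spec.n_planted_hubs else inf_mirnas
    signs = np.array(["activation", "repression", "regulation"])

    def background(kind, n_records, src_pool, dst_pool):
        attempts = 0
        added = 0
        while added < n_records and attempts < 20 * n_records:
            attempts += 1
            s = src_pool[rng.integers(len(src_pool))]
            t = dst_pool[rng.integers(len(dst_pool))]
            if s in protected or t in protected:
                continue
            if degree.get(s, 0) >= cap or degree.get(t, 0) >= cap:
                continue
            add(s, t, kind, signs[rng.integers(3)])
            bump(s, t)
            added += 1

    background("tf_mirna", 40, tf_pool, mir_pool)
    background("mirna_target", 40, mir_pool, target_pool)

    # decoy records that every filter branch must remove
    for i in range(8):
        add(tf_pool[rng.integers(len(tf_pool))],
            mir_pool[rng.integers(len(mir_pool))],
            "tf_mirna", "regulation", evidence="other")
    for i in range(8):
        add(mir_pool[rng.integers(len(mir_pool))],
            target_pool[rng.integers(len(target_pool))],
            "mirna_target", "repression", context="normal")
    for i in range(8):
        add(f"OFFTARGET{i:02d}", mir_pool[rng.integers(len(mir_pool))],
            "tf_mirna", "activation")
        add(mir_pool[rng.integers(len(mir_pool))], f"OFFGENE{i:02d}",
            "mirna_target", "repression")

    records = pd.DataFrame(rows, columns=["source", "target", "kind", "sign",
                                          "evidence", "context"])
    return InteractionTables(records=records, truth=truth)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: MultiOmicsCohort, outdir) -> None:
    """Write all cohort tables as TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, layer in cohort.layers.items():
        layer.to_tsv(outdir / f"{name}.tsv")
    write_annotation(cohort.annotation, outdir / "annotation.tsv")
    clin = cohort.clinical.copy()
    clin.index.name = "patient_id"
    clin.to_csv(outdir / "clinical.tsv", sep="\t")
    dp = cohort.detection_p.to_frame()
    dp.index.name = "patient_id"
    dp.to_csv(outdir / "detection_p.tsv", sep="\t")
    sub = cohort.true_subtype.to_frame()
    sub.index.name = "patient_id"
    sub.to_csv(outdir / "true_subtype.tsv", sep="\t")


def write_interactions(tables: InteractionTables, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables.tf_mirna.to_csv(outdir / "tf_mirna.tsv", sep="\t", index=False)
    tables.mirna_target.to_csv(outdir / "mirna_target.tsv", sep="\t", index=False)


def read_interactions(tf_mirna_path, mirna_target_path) -> pd.DataFrame:
    a = pd.read_csv(tf_mirna_path, sep="\t", dtype=str)
    b = pd.read_csv(mirna_target_path, sep="\t", dtype=str)
    return pd.concat([a, b], ignore_index=True)
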