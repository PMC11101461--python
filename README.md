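# snfmark

Multi-omics biomarker discovery for tumor cohorts by similarity network
fusion (SNF), ranked-SNF feature selection, regulatory-network hub
scoring, and survival validation.

The package is aimed at computational biologists who have
feature-by-patient matrices for several omics layers of the same cohort
(the motivating case is neuroblastoma: 450K methylation beta values,
mRNA-seq FPKM, miRNA-seq expression, plus overall survival and INSS stage)
and want a short, ranked list of candidate biomarker transcription factors
and miRNAs, with every stage testable against a synthetic cohort whose
ground truth is known.

## The method

1. **Preprocess** each layer: drop features with missing values,
   multimapped reporters, sex-chromosome features (methylation/mRNA), and
   all-zero rows; convert FPKM to TPM; min–max scale each feature.
2. **Fuse** the layers. Per layer, a scaled exponential kernel with
   adaptive bandwidth gives patient similarities
   `W(i,j) = exp(−d(i,j)² / (α·ε_ij))`; cross-diffusion
   `P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v} P⁽ᵘ⁾ · S⁽ᵛ⁾ᵀ` over T iterations merges them
   into one fused patient network (defaults k = 20, α = 0.5, T = 15;
   convergence diagnosed by the relative spectral-norm change between
   consecutive fused graphs).
3. **Cluster** the fused network (normalized-Laplacian spectral clustering)
   and pick the number of clusters c maximizing the quality ratio
   `Q = min within-cluster similarity / max between-cluster similarity`
   over c = 2..7.
4. **Rank features** (rSNF): each feature is scored by the normalized
   mutual information between the clustering its own similarity network
   induces and the fused clustering; the top 10% per layer (ceiling rule)
   are selected, mapped to gene symbols, and the genes shared by the
   methylation and mRNA layers become the *essential genes*.
5. **Build the regulatory network** from TF→miRNA and miRNA→target
   interaction tables restricted to essential genes and high-rank miRNAs
   (level-2/literature evidence, tumor context only) and rank hubs by
   Maximal Clique Centrality, `MCC(v) = Σ_{cliques C∋v} (|C|−1)!`.
6. **Validate** each hub: dichotomize expression at mean ± 0.25·SD,
   compare the groups by Kaplan–Meier/log-rank, test stage association by
   chi-square, and quantify diagnostic discrimination by the rank-statistic
   ROC AUC.

See `docs/methods.md` for the full model description, parameter defaults,
and the design choices behind them.

## Worked example

Run the whole pipeline on a small synthetic cohort (60 patients, 4 planted
subtypes, 300 features per layer):

```python
from snfmark import CohortSpec, PipelineConfig, run
from snfmark.snf import SnfParams

config = PipelineConfig(
    cohort_spec=CohortSpec(n_patients=60, n_methylation=300, n_mrna=300,
                           n_mirna=300, seed=5),
    snf_params=SnfParams(k=10, T=15),
    seed=5,
    outdir="demo_output",
)
summary = run(config)
print("selected clusters:", summary["c_star"])
print("Q profile:", {c: round(q, 3) for c, q in summary["q_profile"].items()})
print("subtype recovery NMI:", round(summary["subtype_recovery_nmi"], 3))
print("essential genes:", summary["n_essential_genes"])
print("network:", summary["network"])
print("top hub:", summary["top_hubs"][0])
```

which prints:

```
selected clusters: 4
Q profile: {'2': 0.287, '3': 0.369, '4': 0.564, '5': 0.469, '6': 0.415, '7': 0.458}
subtype recovery NMI: 0.91
essential genes: 20
network: {'n_nodes': 46, 'n_edges': 72, 'n_records_kept': 75}
top hub: {'node': 'GENE00005', 'role': 'TF', 'mcc': 12, 'degree': 12, 'rank': 1}
```

The Q profile peaks at c = 4, recovering the four planted subtypes (NMI
0.91 against the ground truth); the 20 essential genes are the planted
informative genes recovered in both gene-bearing layers; and the top hub of
the regulatory network is the generator's planted hub TF, whose MCC of 12
equals its degree (a TF–miRNA–gene graph is bipartite, so no node lies on
a triangle). `demo_output/` additionally holds the fused similarity
matrix, per-layer rankings, the network in SIF/GraphML, the hub table, the
validation panel (log-rank, chi-square, AUC per hub), and a byte-stable
`summary.json`.

The same pipeline is available from the shell, stage by stage or end to
end:

```sh
snfmark simulate --out data --seed 5 --n-patients 60
snfmark preprocess --data data --workdir work
snfmark fuse --workdir work
snfmark cluster --workdir work
snfmark rank --data data --workdir work
snfmark network --data data --workdir work
snfmark validate --data data --workdir work
# or all at once:
snfmark run-all --out results_dir --seed 5
```

User-supplied data replaces the simulator by pointing `PipelineConfig`
(`data_dir=...`) or the CLI `--data` at a directory of TSV tables in the
layout written by `snfmark simulate`.

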