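"""TF–gene–miRNA regulatory network construction and hub ranking.

Interaction records come from TransmiR-style TF→miRNA tables and
TarBase-style miRNA→target tables.  Records are kept only when their
endpoints fall in the selected sets (essential genes, high-rank miRNAs),
their evidence is ChIP-seq level-2 or literature-curated, and their cellular
context is tumor-derived.  The surviving records form a directed signed
graph; hubs are ranked by Maximal Clique Centrality on the undirected simple
projection: MCC(v) = Σ_{maximal cliques C ∋ v, |C| ≥ 2} (|C| − 1)!.  For a
node that lies on no triangle — in particular every node of the strictly
bipartite TF/gene vs miRNA topology produced here — MCC reduces to degree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "HubScore",
    "filter_interactions",
    "build_network",
    "mcc_scores",
    "top_hubs",
    "write_sif",
    "write_graphml",
]

REQUIRED_COLUMNS = ("source", "target", "kind", "sign", "evidence", "context")

VALID_KINDS = {"tf_mirna", "mirna_target"}
VALID_SIGNS = {"activation", "repression", "regulation"}
KEPT_EVIDENCE = {"level2", "literature"}


@dataclass(frozen=True)
class HubScore:
    node: str
    role: str
    mcc: int
    degree: int
    rank: int


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    bad = set(records["kind"]) - VALID_KINDS
    if bad:
        raise ValueError(f"unknown interaction kinds: {bad}")


def filter_interactions(records: pd.DataFrame, highrank_mirnas: set[str],
                        essential: set[str]) -> pd.DataFrame:
    """Keep interactions linking the selected molecular sets.

    TF→miRNA records survive when the TF is an essential gene and the miRNA
    is high-rank; miRNA→target records when the miRNA is high-rank and the
    target is an essential gene.  Evidence ``other`` and normal-cell-line
    context are dropped.
    """
    _check_records(records)
    if not highrank_mirnas or not essential:
        raise ValueError("high-rank miRNA and essential gene sets must be nonempty")
    r = records
    quality = r["evidence"].isin(KEPT_EVIDENCE) & (r["context"] != "normal")
    tf = (r["kind"] == "tf_mirna") & r["source"].isin(essential) \
        & r["target"].isin(highrank_mirnas)
    mt = (r["kind"] == "mirna_target") & r["source"].isin(highrank_mirnas) \
        & r["target"].isin(essential)
    return r[quality & (tf | mt)].reset_index(drop=True)


def _merge_signs(signs: list[str]) -> tuple[str, bool]:
    """Collapse duplicate-edge signs: specific beats generic 'regulation';
    conflicting activation vs repression is kept as 'ambiguous'."""
    specific = {s for s in signs if s in ("activation", "repression")}
    if len(specific) > 1:
        return "ambiguous", True
    if len(specific) == 1:
        return next(iter(specific)), False
    return "regulation", False


def build_network(records: pd.DataFrame) -> nx.DiGraph:
    """Directed signed graph from filtered interaction records.

    Node roles: sources of TF→miRNA records are TFs; miRNAs come from either
    record kind; targets of miRNA→target records are genes.  A symbol acting
    both as TF and as target gene keeps the TF role.  Parallel edges are
    collapsed by the sign-merge rule; self-loops are rejected.
    """
    _check_records(records)
    if len(records) == 0:
        warnings.warn("no interaction records; building an empty network",
                      stacklevel=2)
    if (records["source"] == records["target"]).any():
        raise ValueError("self-loop in interaction records")
    G = nx.DiGraph()
    roles: dict[str, str] = {}
    for row in records.itertuples(index=False):
        src, dst = str(row.source), str(row.target)
        if row.kind == "tf_mirna":
            roles[src] = "TF"  # TF beats gene
            roles.setdefault(dst, "miRNA")
        else:
            roles.setdefault(src, "miRNA")
            roles.setdefault(dst, roles.get(dst, "gene"))
    grouped = records.groupby(["source", "target", "kind"], sort=True)["sign"]
    for (src, dst, kind), signs in grouped:
        sign, ambiguous = _merge_signs([str(s) for s in signs])
        G.add_edge(str(src), str(dst), kind=str(kind), sign=sign,
                   ambiguous=ambiguous)
    for node, role in roles.items():
        if node in G:
            G.nodes[node]["role"] = role
    return G


def mcc_scores(net: nx.DiGraph | nx.Graph) -> pd.DataFrame:
    """Maximal Clique Centrality of every node.

    Computed on the undirected simple projection (direction and sign are
    topology-irrelevant for clique membership).  Maximal cliques are
    enumerated exactly (Bron–Kerbosch with pivoting); singleton cliques are
    excluded, so isolated nodes score 0 and triangle-free nodes score their
    degree.  Worst case is exponential; regulatory networks here are sparse.
    """
    U = net.to_undirected() if net.is_directed() else net.copy()
    scores = {v: 0 for v in U.nodes}
    for clique in nx.find_cliques(U):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    rows = [
        {
            "node": v,
            "role": U.nodes[v].get("role", ""),
            "mcc": s,
            "degree": U.degree(v),
        }
        for v, s in scores.items()
    ]
    df = pd.DataFrame(rows, columns=["node", "role", "mcc", "degree"])
    df = df.sort_values(["mcc", "degree", "node"], ascending=[False, False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def top_hubs(scores: pd.DataFrame, n: int = 10) -> list[HubScore]:
    """Top-``n`` nodes by MCC; ties by degree, then symbol order.

    Returns all nodes when fewer than ``n`` exist.
    """
    head = scores.head(n)
    return [
        HubScore(node=r.node, role=r.role, mcc=int(r.mcc),
                 degree=int(r.degree), rank=int(r.rank))
        for r in head.itertuples(index=False)
    ]


def write_sif(net: nx.DiGraph, path) -> None:
    """Cytoscape SIF export: source <tab> sign <tab> target."""
    with open(path, "w") as fh:
        for src, dst, data in net.edges(data=True):
            fh.write(f"{src}\t{data.get('sign', 'regulation')}\t{dst}\n")


def write_graphml(net: nx.DiGraph, path) -> None:
    nx.write_graphml(net, path)


def write_hub_table(hubs: list[HubScore], path) -> None:
    pd.DataFrame([h.__dict__ for h in hubs]).to_csv(path, sep="\t", index=False)
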