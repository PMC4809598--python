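"""Annotated gene-network assembly, summary statistics, TF subnetwork
extraction, Fisher's-exact over-representation, and standard-format export.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

NODE_CLASSES = ("is_de", "is_ts", "is_tf", "is_snp")


@dataclass
class GeneNetwork:
    """Node table + undirected weighted edge list.

    Node classes are non-exclusive boolean flags; ``tissue`` is the tissue
    of highest relative expression (attached for every node, TS or not).
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        endpoints = pd.Index(self.edges["gene_a"]).union(pd.Index(self.edges["gene_b"]))
        missing = endpoints.difference(self.nodes.index)
        if len(missing):
            raise ValidationError(f"edge endpoints missing from node table: {missing.tolist()[:10]}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for gene, row in self.nodes.iterrows():
            g.add_node(gene, **{k: row[k] for k in self.nodes.columns})
        for _, row in self.edges.iterrows():
            g.add_edge(row["gene_a"], row["gene_b"], weight=float(row.get("r", 1.0)))
        return g


def build_network(
    edges: pd.DataFrame,
    de_genes: Iterable,
    ts_genes: Iterable,
    tf_genes: Iterable,
    snp_genes: Iterable,
    tissue_of_max: pd.Series,
    provenance: Optional[dict] = None,
) -> GeneNetwork:
    """Assemble the network over the DE|TS|TF|SNP node union.

    Only accepted edges are kept; edges touching genes outside the node
    union are dropped.  ``tissue_of_max`` maps gene -> tissue of highest
    relative expression (used for node colouring and tissue summaries).
    """
    de, ts = pd.Index(de_genes), pd.Index(ts_genes)
    tf, snp = pd.Index(tf_genes), pd.Index(snp_genes)
    node_ids = de.union(ts).union(tf).union(snp)
    if len(node_ids) == 0:
        raise ValidationError("empty node union")
    nodes = pd.DataFrame(
        {
            "is_de": node_ids.isin(de),
            "is_ts": node_ids.isin(ts),
            "is_tf": node_ids.isin(tf),
            "is_snp": node_ids.isin(snp),
            "tissue": tissue_of_max.reindex(node_ids),
        },
        index=node_ids,
    )
    nodes.index.name = "gene"
    if "accepted" in edges.columns:
        edges = edges[edges["accepted"].astype(bool)]
    keep = edges["gene_a"].isin(node_ids) & edges["gene_b"].isin(node_ids)
    edges = edges.loc[keep].reset_index(drop=True)
    ga = edges["gene_a"].astype(str).to_numpy()
    gb = edges["gene_b"].astype(str).to_numpy()
    swap = ga > gb
    edges = edges.assign(gene_a=np.where(swap, gb, ga), gene_b=np.where(swap, ga, gb))
    if edges.duplicated(subset=["gene_a", "gene_b"]).any():
        edges = edges.drop_duplicates(subset=["gene_a", "gene_b"]).reset_index(drop=True)
    return GeneNetwork(nodes=nodes, edges=edges, provenance=provenance or {})


def degree_table(net: GeneNetwork) -> pd.DataFrame:
    """Per-node degree, ranked descending with stable tie-break by gene id."""
    counts = pd.concat([net.edges["gene_a"], net.edges["gene_b"]]).value_counts()
    degree = counts.reindex(net.nodes.index).fillna(0).astype(int)
    out = pd.DataFrame({"degree": degree, "tissue": net.nodes["tissue"]})
    out.index.name = "gene"
    return out.sort_values(["degree", "gene"], ascending=[False, True], kind="mergesort")


def tissue_edge_summary(net: GeneNetwork) -> dict:
    """Within-tissue edge fraction, per-tissue counts, and the R^2 of
    inter-tissue edge count regressed on node count."""
    tissue = net.nodes["tissue"]
    ta = net.edges["gene_a"].map(tissue)
    tb = net.edges["gene_b"].map(tissue)
    n_edges = len(net.edges)
    within = (ta == tb) if n_edges else pd.Series(dtype=bool)
    within_fraction = float(within.mean()) if n_edges else float("nan")
    node_counts = tissue.value_counts().sort_index()
    per_tissue = pd.DataFrame({"nodes": node_counts})
    per_tissue["within_edges"] = pd.Series(
        ta[within].value_counts() if n_edges else {}, dtype=float
    ).reindex(node_counts.index).fillna(0).astype(int)
    inter = pd.Series(0, index=node_counts.index, dtype=int)
    if n_edges:
        cross = ~within
        inter = (
            pd.concat([ta[cross], tb[cross]]).value_counts()
            .reindex(node_counts.index).fillna(0).astype(int)
        )
    per_tissue["inter_edges"] = inter
    r2 = float("nan")
    if len(node_counts) >= 3 and per_tissue["inter_edges"].var() > 0 and per_tissue["nodes"].var() > 0:
        res = stats.linregress(per_tissue["nodes"], per_tissue["inter_edges"])
        r2 = float(res.rvalue**2)
    return {
        "within_fraction": within_fraction,
        "per_tissue": per_tissue,
        "inter_edge_r2": r2,
    }


def class_edge_summary(net: GeneNetwork) -> pd.Series:
    """Fraction of edges by endpoint class pattern (TS-TS, TS-other, class shares)."""
    flags = net.nodes[list(NODE_CLASSES)]
    fa = flags.loc[net.edges["gene_a"]].reset_index(drop=True)
    fb = flags.loc[net.edges["gene_b"]].reset_index(drop=True)
    n = max(len(net.edges), 1)
    out = {
        "ts_ts": float((fa["is_ts"] & fb["is_ts"]).sum() / n),
        "ts_other": float(((fa["is_ts"] ^ fb["is_ts"])).sum() / n),
    }
    for cls in NODE_CLASSES:
        out[f"touching_{cls[3:]}"] = float((fa[cls] | fb[cls]).sum() / n)
    return pd.Series(out)


def extract_tf_subnetwork(net: GeneNetwork) -> GeneNetwork:
    """Nodes = TFs plus their neighbours; edges = edges incident to a TF."""
    tf_nodes = net.nodes.index[net.nodes["is_tf"]]
    if len(tf_nodes) == 0:
        logger.warning("no TF nodes: returning an empty subnetwork")
        return GeneNetwork(nodes=net.nodes.iloc[0:0], edges=net.edges.iloc[0:0],
                           provenance=dict(net.provenance))
    incident = net.edges["gene_a"].isin(tf_nodes) | net.edges["gene_b"].isin(tf_nodes)
    edges = net.edges[incident].reset_index(drop=True)
    neighbours = pd.Index(edges["gene_a"]).union(pd.Index(edges["gene_b"]))
    keep = pd.Index(tf_nodes).union(neighbours)
    return GeneNetwork(nodes=net.nodes.loc[keep], edges=edges,
                       provenance=dict(net.provenance))


def fisher_enrichment(
    gene_set: Iterable,
    universe: Iterable,
    term_map: Mapping,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher's exact test per term.

    ``term_map`` maps gene -> iterable of term ids.  The hypergeometric
    upper tail P(X >= k) is computed for each term with k = |set & term|,
    K = |universe & term|, n = |set|, N = |universe|.  No multiple-testing
    correction is applied (flagging uses raw p < alpha).
    """
    universe = pd.Index(universe).unique()
    if len(universe) == 0:
        raise ValidationError("empty universe")
    gene_set = pd.Index(gene_set).unique()
    if not gene_set.isin(universe).all():
        raise ValidationError("gene_set must be a subset of the universe")
    terms: Dict[object, set] = {}
    for gene in universe:
        for term in term_map.get(gene, ()):  # genes without terms contribute nothing
            terms.setdefault(term, set()).add(gene)
    N, n = len(universe), len(gene_set)
    set_lookup = set(gene_set)
    rows = []
    for term, members in sorted(terms.items(), key=lambda kv: str(kv[0])):
        K = len(members)
        k = len(members & set_lookup)
        # upper tail inclusive of k: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "set_in_term": k,
                "set_not_in_term": n - k,
                "universe_in_term": K,
                "universe_not_in_term": N - K,
                "p_value": min(p, 1.0),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows, columns=["term", "set_in_term", "set_not_in_term",
                                       "universe_in_term", "universe_not_in_term",
                                       "p_value", "significant"])


def export_network(net: GeneNetwork, path: str | Path, fmt: str = "tsv") -> Path:
    """Write the network as SIF, TSV (nodes + edges), or GraphML."""
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for _, row in net.edges.iterrows():
                fh.write(f"{row['gene_a']}\tco\t{row['gene_b']}\n")
    elif fmt == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
        nodes_path = path.with_name(path.stem + "_nodes.tsv")
        net.nodes.to_csv(nodes_path, sep="\t")
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    return path


def read_network_tsv(edges_path: str | Path, nodes_path: str | Path | None = None) -> GeneNetwork:
    """Round-trip reader for the TSV export."""
    edges_path = Path(edges_path)
    edges = pd.read_csv(edges_path, sep="\t")
    if "accepted" in edges.columns:
        edges["accepted"] = edges["accepted"].astype(bool)
    if nodes_path is None:
        nodes_path = edges_path.with_name(edges_path.stem + "_nodes.tsv")
    nodes = pd.read_csv(nodes_path, sep="\t", index_col=0)
    for cls in NODE_CLASSES:
        if cls in nodes.columns:
            nodes[cls] = nodes[cls].astype(bool)
    return GeneNetwork(nodes=nodes, edges=edges)
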