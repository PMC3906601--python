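"""Heterogeneous (bipartite feature--gene) association networks.

Nodes are genes or genomic features (CNA cytobands, methylation features,
miRNAs); an edge joins a feature to a gene it is associated with, weighted
by association strength.  Node ids are prefixed with their type
("gene:TP53", "methylation:SPRY4") so that a methylation feature and the
gene of the same symbol remain distinct nodes.

Because the graph is strictly bipartite the triangle clustering coefficient
is identically zero, so the square-based bipartite clustering coefficient is
reported instead.  Modularity is Newman's Q under the partition found by
greedy (CNM) agglomeration on the unweighted graph.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

GENE = "gene"
FORMATS = ("sif", "graphml", "tsv")


def _fnode(feature_id: str, feature_type: str) -> str:
    return f"{feature_type}:{feature_id}"


def _gnode(gene_id: str) -> str:
    return f"{GENE}:{gene_id}"


def strip_prefix(node: str) -> str:
    return node.split(":", 1)[1]


def build_network(edges: pd.DataFrame, rho: float = 0.3) -> nx.Graph:
    """Bipartite association network over edges with strength >= rho.

    Nodes carry a ``node_type`` attribute (gene | CNA | methylation | miRNA);
    edges carry ``weight`` (strength), ``p_value`` and ``feature_type``.
    Isolated nodes never arise (nodes exist only as edge endpoints).  An
    empty network is allowed but warned about.
    """
    g = nx.Graph()
    kept = edges[edges["strength"] >= rho] if not edges.empty else edges
    if kept.empty:
        warnings.warn(f"no association edge reaches rho={rho}; network is empty")
        return g
    kept = kept.sort_values(
        ["feature_type", "feature_id", "gene_id"], kind="mergesort"
    )
    for row in kept.itertuples(index=False):
        u = _fnode(row.feature_id, row.feature_type)
        v = _gnode(row.gene_id)
        g.add_node(u, node_type=row.feature_type)
        g.add_node(v, node_type=GENE)
        g.add_edge(
            u, v,
            weight=float(row.strength),
            p_value=float(row.p_value),
            feature_type=row.feature_type,
        )
    return g


def is_bipartite_feature_gene(g: nx.Graph) -> bool:
    """Every edge must join a feature node to a gene node."""
    return all(
        (g.nodes[u]["node_type"] == GENE) != (g.nodes[v]["node_type"] == GENE)
        for u, v in g.edges
    )


def _components(g: nx.Graph) -> list[set[str]]:
    comps = list(nx.connected_components(g))
    # deterministic: largest first, ties by lexicographically smallest node set
    return sorted(comps, key=lambda c: (-len(c), tuple(sorted(c))))


def topology_summary(g: nx.Graph) -> dict:
    """Global diagnostics: component structure, bipartite (square)
    clustering, and greedy-partition modularity Q with its communities."""
    if g.number_of_nodes() == 0:
        raise ValueError("topology summary of an empty network")
    comps = _components(g)
    sq = nx.square_clustering(g)
    if g.number_of_edges() > 0:
        communities = [
            set(c) for c in nx.community.greedy_modularity_communities(g, weight=None)
        ]
        q = nx.community.modularity(g, communities, weight=None)
    else:
        communities = [set(c) for c in comps]
        q = float("nan")
    return {
        "n_components": len(comps),
        "component_sizes": [len(c) for c in comps],
        "largest_component_nodes": sorted(comps[0]),
        "square_clustering": sq,
        "mean_square_clustering": float(np.mean(list(sq.values()))) if sq else 0.0,
        "modularity": float(q),
        "communities": [sorted(c) for c in communities],
    }


def largest_component_genes(g: nx.Graph) -> list[str]:
    """Gene ids (unprefixed) of the largest connected component; size ties
    break to the lexicographically smallest node set."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty network has no components")
    comp = _components(g)[0]
    return sorted(
        strip_prefix(n) for n in comp if g.nodes[n]["node_type"] == GENE
    )


def modularity(g: nx.Graph) -> float:
    if g.number_of_edges() == 0:
        return float("nan")
    communities = nx.community.greedy_modularity_communities(g, weight=None)
    return float(nx.community.modularity(g, communities, weight=None))


# ---------------------------------------------------------------------------
# Export / import


def _sorted_edges(g: nx.Graph):
    return sorted((min(u, v), max(u, v)) for u, v in g.edges)


def export_network(g: nx.Graph, path, fmt: str) -> Path:
    """Write the network in a Cytoscape-readable format with byte-stable
    ordering.  ``sif`` lines read "feature <feature_type> gene" (attributes
    beyond the relation are not representable in SIF); ``graphml`` and
    ``tsv`` carry node types, weights and p-values losslessly."""
    path = Path(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format '{fmt}'; expected one of {FORMATS}")
    if fmt == "sif":
        lines = []
        for u, v in _sorted_edges(g):
            feat, gene = (u, v) if g.nodes[u]["node_type"] != GENE else (v, u)
            lines.append(f"{feat}\t{g.edges[u, v]['feature_type']}\t{gene}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "tsv":
        rows = []
        for u, v in _sorted_edges(g):
            feat, gene = (u, v) if g.nodes[u]["node_type"] != GENE else (v, u)
            d = g.edges[u, v]
            rows.append(
                (strip_prefix(feat), d["feature_type"], strip_prefix(gene),
                 d["weight"], d["p_value"])
            )
        pd.DataFrame(
            rows, columns=["feature_id", "feature_type", "gene_id", "weight", "p_value"]
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        h = nx.Graph()
        for n in sorted(g.nodes):
            h.add_node(n, node_type=g.nodes[n]["node_type"])
        for u, v in _sorted_edges(g):
            h.add_edge(u, v, **g.edges[u, v])
        nx.write_graphml(h, path, named_key_ids=True)
    return path


def import_network(path, fmt: str) -> nx.Graph:
    """Read back a network written by :func:`export_network`."""
    path = Path(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format '{fmt}'; expected one of {FORMATS}")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for n, d in g.nodes(data=True):
            out.add_node(str(n), node_type=d["node_type"])
        for u, v, d in g.edges(data=True):
            out.add_edge(
                str(u), str(v),
                weight=float(d["weight"]),
                p_value=float(d["p_value"]),
                feature_type=d["feature_type"],
            )
        return out
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            u = _fnode(row.feature_id, row.feature_type)
            v = _gnode(row.gene_id)
            g.add_node(u, node_type=row.feature_type)
            g.add_node(v, node_type=GENE)
            g.add_edge(
                u, v,
                weight=float(row.weight),
                p_value=float(row.p_value),
                feature_type=row.feature_type,
            )
        return g
    g = nx.Graph()
    text = path.read_text()
    for line in text.splitlines():
        if not line.strip():
            continue
        feat, ftype, gene = line.split("\t")
        g.add_node(feat, node_type=ftype)
        g.add_node(gene, node_type=GENE)
        g.add_edge(feat, gene, feature_type=ftype)
    return g
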