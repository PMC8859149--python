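"""PPI graph handling and hub-gene selection.

Edge lists arrive as STRING-style TSV (node_a, node_b, optional confidence
score) and are filtered at a confidence threshold (default 0.7).  Four
node centralities are computed — Degree, MCC (maximal clique centrality),
DMNC (density of the maximum neighborhood component) and EPC (edge
percolated component) — and hub genes are the intersection of the top-k
lists of all four with the top-k aggregated DEGs.

Centrality definitions follow the cytoHubba conventions:

* MCC(v)  = sum over maximal cliques C containing v (|C| >= 2) of (|C|-1)!;
  a node whose neighborhood has no edges scores its degree (each incident
  edge is itself a maximal 2-clique), and an isolated node scores 0.
* DMNC(v) = |E| / |V|**epsilon of the largest connected component of the
  subgraph induced by v's neighbors (v excluded), epsilon = 1.7 by default.
* EPC(v)  = mean, over random subgraphs keeping each edge independently
  with probability ``keep_prob``, of the number of other nodes in v's
  connected component.
"""

from __future__ import annotations

from math import factorial
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "load_edges",
    "write_edges",
    "degree",
    "mcc",
    "dmnc",
    "epc",
    "centrality_table",
    "top_k",
    "rra_top_genes",
    "hub_genes",
]


def load_edges(path, score_threshold: float = 0.7, nodes_path=None) -> nx.Graph:
    """Read a TSV edge list into a simple undirected graph.

    Columns: node_a, node_b, optional confidence score.  Scores on
    STRING's 0-1000 scale (detected when any score exceeds 1) are divided
    by 1000.  Edges with score >= ``score_threshold`` are retained;
    self-loops are dropped and duplicate edges collapse to one (keeping
    the highest score).  ``nodes_path`` may list additional node ids to
    keep even if isolated.
    """
    path = Path(path)
    edges: list[tuple[str, str, float | None]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two columns")
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty node id")
            score = None
            if len(parts) >= 3 and parts[2].strip():
                try:
                    score = float(parts[2])
                except ValueError as err:
                    if lineno == 1:  # header row
                        continue
                    raise ValueError(
                        f"{path}:{lineno}: malformed score {parts[2]!r}"
                    ) from err
            edges.append((a, b, score))

    scores = [s for _, _, s in edges if s is not None]
    scale = 1000.0 if scores and max(scores) > 1.0 else 1.0

    g = nx.Graph()
    for a, b, s in edges:
        if a == b:
            continue
        conf = 1.0 if s is None else s / scale
        if conf >= score_threshold:
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], conf)
            else:
                g.add_edge(a, b, score=conf)
    if nodes_path is not None:
        with open(nodes_path, encoding="utf-8") as fh:
            for line in fh:
                node = line.strip()
                if node:
                    g.add_node(node)
    return g


def write_edges(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tscore\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('score', 1.0):g}\n")


def degree(graph: nx.Graph) -> pd.Series:
    """Incident edge count per node."""
    return pd.Series(dict(graph.degree()), dtype=float).sort_index()


def mcc(graph: nx.Graph, node_limit: int = 5000) -> pd.Series:
    """Maximal clique centrality via Bron-Kerbosch enumeration.

    Guarded by ``node_limit`` because maximal-clique enumeration is
    exponential in the worst case.
    """
    if graph.number_of_nodes() > node_limit:
        raise ValueError(
            f"graph has {graph.number_of_nodes()} nodes; raise node_limit to force"
        )
    scores = {v: 0.0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        w = float(factorial(len(clique) - 1))
        for v in clique:
            scores[v] += w
    return pd.Series(scores, dtype=float).sort_index()


def dmnc(graph: nx.Graph, epsilon: float = 1.7) -> pd.Series:
    """Density of the maximum neighborhood component per node.

    Zero when the neighborhood has no edges.  The largest component is
    chosen by node count, ties broken by edge count then node ids, for
    determinism.
    """
    scores = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        sub = graph.subgraph(nbrs)
        best_val = 0.0
        comps = sorted(
            nx.connected_components(sub),
            key=lambda c: (-len(c), -sub.subgraph(c).number_of_edges(), sorted(c)),
        )
        if comps:
            comp = sub.subgraph(comps[0])
            e, nn = comp.number_of_edges(), comp.number_of_nodes()
            if e > 0:
                best_val = e / nn**epsilon
        scores[v] = best_val
    return pd.Series(scores, dtype=float).sort_index()


def epc(
    graph: nx.Graph,
    n_realizations: int = 1000,
    keep_prob: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Edge percolated component score per node.

    Averages, over ``n_realizations`` Bernoulli edge-subsampled copies of
    the graph, the number of other nodes sharing a component with each
    node.  Deterministic under ``seed``; scores lie in [0, |V|-1].
    """
    if n_realizations < 1:
        raise ValueError(f"n_realizations must be >= 1, got {n_realizations}")
    if not 0.0 <= keep_prob <= 1.0:
        raise ValueError(f"keep_prob must be in [0, 1], got {keep_prob}")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    nv = len(nodes)
    if nv == 0:
        return pd.Series(dtype=float)
    edges = np.array(
        [[index[a], index[b]] for a, b in graph.edges], dtype=np.intp
    ).reshape(-1, 2)
    ne = edges.shape[0]
    rng = np.random.default_rng(seed)
    totals = np.zeros(nv)
    for _ in range(n_realizations):
        kept = edges[rng.random(ne) < keep_prob] if ne else edges[:0]
        data = np.ones(kept.shape[0])
        adj = coo_matrix((data, (kept[:, 0], kept[:, 1])), shape=(nv, nv))
        _, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels, minlength=labels.max() + 1)
        totals += sizes[labels] - 1
    return pd.Series(totals / n_realizations, index=nodes, dtype=float)


def centrality_table(
    graph: nx.Graph,
    epsilon: float = 1.7,
    n_realizations: int = 1000,
    keep_prob: float = 0.5,
    seed: int = 0,
    node_limit: int = 5000,
) -> pd.DataFrame:
    """Degree/MCC/DMNC/EPC for every node, as one table."""
    table = pd.DataFrame(
        {
            "degree": degree(graph),
            "mcc": mcc(graph, node_limit=node_limit),
            "dmnc": dmnc(graph, epsilon=epsilon),
            "epc": epc(graph, n_realizations=n_realizations, keep_prob=keep_prob, seed=seed),
        }
    )
    table.index.name = "gene_id"
    return table


def top_k(scores: Mapping[str, float] | pd.Series, k: int = 100) -> list[str]:
    """Top-k node ids by descending score, ties by ascending id; all if fewer."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    items = list(scores.items())
    ordered = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    return [v for v, _ in ordered[:k]]


def rra_top_genes(up, down, k: int = 100) -> list[str]:
    """Best k aggregated genes pooling the up and down tables by exact p-value."""
    pooled = pd.concat(
        [up.table[["exact_p"]], down.table[["exact_p"]]]
    )
    # a gene can only appear in one direction's top region; if duplicated,
    # keep its more significant entry
    pooled = pooled.groupby(level=0).min()
    ordered = sorted(pooled.index, key=lambda g: (pooled.at[g, "exact_p"], g))
    return ordered[:k]


def hub_genes(
    centralities: pd.DataFrame, rra_top: Sequence[str], k: int = 100
) -> list[str]:
    """5-way intersection: top-k of each centrality and the top-k aggregated genes."""
    sets = [set(top_k(centralities[col], k)) for col in ("degree", "mcc", "dmnc", "epc")]
    sets.append(set(list(rra_top)[:k]))
    return sorted(set.intersection(*sets))
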