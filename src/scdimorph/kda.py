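"""Key-driver analysis: which network nodes have DEG-enriched neighborhoods?

Given a gene regulatory network and a DEG set, each node with at least
``min_neighbors`` neighbours is scored by a chi-square-like standardized
excess X = (O - E) / sqrt(E + kappa), where O is the number of DEGs among its
neighbours (within ``depth`` edges, undirected reachability), and
E = m * D / V is the count expected if the D network DEGs were spread
uniformly over the V nodes. Significance comes from a one-sided permutation
null that re-draws the DEG labels uniformly over nodes (preserving D),
followed by BH FDR across scored nodes; key drivers are called at FDR < 0.05.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

DEFAULT_KAPPA = 1.0
DEFAULT_MIN_NEIGHBORS = 5


def neighborhood(network: nx.Graph, node: str, depth: int = 1) -> set[str]:
    """Nodes reachable from ``node`` within ``depth`` edges, excluding itself.

    Edge direction is ignored for reachability.
    """
    if node not in network:
        raise KeyError(f"unknown node {node!r}")
    g = network.to_undirected(as_view=True) if network.is_directed() else network
    reach = nx.single_source_shortest_path_length(g, node, cutoff=depth)
    reach.pop(node, None)
    return set(reach)


def _neighborhood_matrix(network: nx.Graph, nodes: list[str], depth: int) -> sp.csr_matrix:
    """Boolean (nodes x nodes) matrix: row i marks the depth-neighbourhood of node i."""
    index = {n: i for i, n in enumerate(nodes)}
    if depth == 1:
        g = network.to_undirected(as_view=True) if network.is_directed() else network
        adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=np.float64)
        adj.setdiag(0)
        adj.eliminate_zeros()
        adj.data[:] = 1.0
        return sp.csr_matrix(adj)
    rows, cols = [], []
    for n in nodes:
        for m in neighborhood(network, n, depth):
            rows.append(index[n])
            cols.append(index[m])
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))


def load_network(edges: pd.DataFrame, directed: bool = False) -> nx.Graph:
    """Build a network from an edge table (source, target[, weight]).

    Self-loops are dropped (their count is stored in ``graph.graph['n_self_loops']``).
    """
    g = nx.DiGraph() if directed else nx.Graph()
    n_self = 0
    for row in edges.itertuples(index=False):
        s, t = str(row[0]), str(row[1])
        if s == t:
            n_self += 1
            continue
        w = float(row[2]) if len(row) > 2 else 1.0
        g.add_edge(s, t, weight=w)
    g.graph["n_self_loops"] = n_self
    return g


def kda_scan(
    network: nx.Graph,
    deg_set: set[str] | list[str],
    depth: int = 1,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    n_perm: int = 1000,
    kappa: float = DEFAULT_KAPPA,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score every eligible node for DEG enrichment in its neighbourhood.

    Returns one row per node with neighbourhood size ``m``, observed DEG count
    ``O``, expectation ``E = m * D / V``, the statistic ``X``, permutation
    ``p = (1 + #{X_perm >= X}) / (1 + n_perm)``, BH ``fdr`` and a
    ``significant`` flag at FDR < 0.05. Nodes with fewer than
    ``min_neighbors`` neighbours are reported with status
    ``"excluded: min neighbors"`` and not scored. The result is invariant to
    node relabelling and edge order, and X is strictly increasing in O at
    fixed m.
    """
    nodes = sorted(network.nodes)
    v = len(nodes)
    deg_in_net = sorted(set(deg_set) & set(nodes))
    d = len(deg_in_net)
    if d == 0:
        raise ValueError("deg_set shares no genes with the network")

    nbm = _neighborhood_matrix(network, nodes, depth)
    m = np.asarray(nbm.sum(axis=1)).ravel()
    eligible = m >= min_neighbors
    if not eligible.any():
        raise ValueError("no nodes meet the min_neighbors requirement")

    is_deg = np.zeros(v)
    is_deg[pd.Index(nodes).get_indexer(deg_in_net)] = 1.0
    o = np.asarray(nbm @ is_deg).ravel()
    e = m * d / v
    x = (o - e) / np.sqrt(e + kappa)

    rng = np.random.default_rng(seed)
    sub = sp.csr_matrix(nbm[eligible])
    m_el, e_el, x_el = m[eligible], e[eligible], x[eligible]
    exceed = np.zeros(int(eligible.sum()))
    chunk = 200
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm_labels = np.zeros((v, b))
        for j in range(b):
            perm_labels[rng.choice(v, size=d, replace=False), j] = 1.0
        o_perm = sub @ perm_labels  # (eligible, b)
        x_perm = (o_perm - e_el[:, None]) / np.sqrt(e_el[:, None] + kappa)
        exceed += (x_perm >= x_el[:, None] - 1e-12).sum(axis=1)
        done += b
    p_el = (1 + exceed) / (1 + n_perm)
    fdr_el = multipletests(p_el, method="fdr_bh")[1]

    out = pd.DataFrame({
        "node": nodes, "m": m.astype(int), "observed": o.astype(int),
        "expected": e, "statistic": x,
        "p": np.nan, "fdr": np.nan, "significant": False,
        "status": np.where(eligible, "ok", "excluded: min neighbors"),
    })
    out.loc[eligible, "p"] = p_el
    out.loc[eligible, "fdr"] = fdr_el
    out.loc[eligible, "significant"] = fdr_el < fdr_threshold
    return out.sort_values(["p", "node"], na_position="last").reset_index(drop=True)


def top_subnetwork(
    network: nx.Graph, kda_table: pd.DataFrame, top_k: int = 5, depth: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge and node tables for the neighbourhoods of the top-k key drivers
    (ranked by p), ready for external graph viewers."""
    scored = kda_table[kda_table["status"] == "ok"].nsmallest(top_k, "p")
    keep: set[str] = set()
    for node in scored["node"]:
        keep |= {node} | neighborhood(network, node, depth)
    sub = network.subgraph(keep)
    edges = pd.DataFrame(
        [(u, v, data.get("weight", 1.0)) for u, v, data in sub.edges(data=True)],
        columns=["source", "target", "weight"],
    )
    nodes = pd.DataFrame({
        "node": sorted(keep),
        "is_key_driver": [n in set(scored["node"]) for n in sorted(keep)],
    })
    return edges, nodes
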