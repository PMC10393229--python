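"""Enrichment-map network over significant pathways, with MCL clustering.

Nodes are significant pathways; two pathways are connected when their gene
overlap score — the average of the Jaccard coefficient |A∩B|/|A∪B| and the
overlap coefficient |A∩B|/min(|A|,|B|) — strictly exceeds a cutoff (default
0.375). Clusters are found with the Markov cluster algorithm (MCL) on the
weighted graph: a column-stochastic transition matrix with self-loops is
alternately expanded (matrix power) and inflated (elementwise power plus
column renormalisation) until convergence; the attractors define the
clusters. Clusters are auto-labelled by their most frequent pathway-name
tokens.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "overlap_score",
    "build_network",
    "mcl_cluster",
    "annotate_clusters",
    "export_network",
]

DEFAULT_STOPWORDS = frozenset(
    "of the and in to a an by for with via on pathway pathways signaling "
    "signalling process regulation response".split()
)


def overlap_score(a, b) -> float:
    """Mean of the Jaccard and overlap coefficients; symmetric, in [0, 1]."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap score undefined for empty sets")
    inter = len(a & b)
    jaccard = inter / len(a | b)
    overlap = inter / min(len(a), len(b))
    return 0.5 * (jaccard + overlap)


def build_network(pathways: pd.DataFrame, threshold: float = 0.375) -> nx.Graph:
    """All-pairs overlap-score graph over pathways.

    ``pathways`` is an ORA result (columns pathway, p, members); an edge is
    added iff the overlap score strictly exceeds ``threshold``. Node
    attributes carry the enrichment P and the member count.
    """
    if len(pathways) == 0:
        raise ValueError("need at least one pathway")
    g = nx.Graph()
    rows = list(pathways.itertuples(index=False))
    for r in rows:
        g.add_node(r.pathway, p=float(r.p), n_members=len(r.members))
    members = {r.pathway: set(r.members) for r in rows}
    for (na, ma), (nb, mb) in itertools.combinations(sorted(members.items()), 2):
        if not ma or not mb:
            continue
        s = overlap_score(ma, mb)
        if s > threshold:
            g.add_edge(na, nb, weight=s)
    return g


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _add_self_loops(W: np.ndarray, scheme) -> np.ndarray:
    W = W.copy()
    n = W.shape[0]
    if scheme == "max":
        incident = W.max(axis=0)
        loops = np.where(incident > 0, incident, 1.0)
    elif scheme == "one":
        loops = np.ones(n)
    else:
        loops = np.full(n, float(scheme))
    W[np.diag_indices(n)] = loops
    return W


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    colsum = M.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return M / colsum


def mcl_cluster(
    network: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    self_loops="max",
) -> tuple[dict, bool]:
    """Markov cluster algorithm on a weighted graph; deterministic.

    Self-loop weight defaults to each node's maximum incident edge weight
    (1 for isolated nodes); ``self_loops`` may also be ``"one"`` or a float.
    Returns (node -> cluster id mapping with ids numbered in sorted-node
    order, converged flag). Non-convergence returns the current partition
    with ``converged=False``.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(network.nodes)
    n = len(nodes)
    if n == 0:
        return {}, True
    W = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    M = _normalize_columns(_add_self_loops(W, self_loops))
    converged = False
    for _ in range(max_iter):
        last = M
        M = np.linalg.matrix_power(M, expansion)
        M = _normalize_columns(np.power(M, inflation))
        if np.abs(M - last).max() < tol:
            converged = True
            break

    # attractors: nodes with mass on their own diagonal; each attractor row's
    # support is one cluster; overlapping supports merge into one cluster
    eps = max(tol, 1e-9)
    attractors = [i for i in range(n) if M[i, i] > eps]
    raw_clusters = [set(np.nonzero(M[i] > eps)[0]) | {i} for i in attractors]
    merged: list[set] = []
    for c in raw_clusters:
        hit = [m for m in merged if m & c]
        for m in hit:
            merged.remove(m)
            c = c | m
        merged.append(c)
    assigned = set().union(*merged) if merged else set()
    for i in range(n):
        if i not in assigned:
            merged.append({i})
    # deterministic cluster ids: order by smallest member index
    merged.sort(key=lambda c: min(c))
    labels = {}
    for cid, c in enumerate(merged):
        for i in c:
            labels[nodes[i]] = cid
    return labels, converged


def annotate_clusters(
    network: nx.Graph,
    clusters: dict,
    n_tokens: int = 3,
    stopwords=DEFAULT_STOPWORDS,
) -> dict[int, str]:
    """Label each cluster by its ``n_tokens`` most frequent name tokens.

    Tokens are lowercase words from member pathway names, minus stopwords;
    frequency ties break alphabetically, so the labels are deterministic
    under node reordering.
    """
    by_cluster: dict[int, list[str]] = {}
    for node, cid in clusters.items():
        by_cluster.setdefault(cid, []).append(str(node))
    labels = {}
    for cid, names in by_cluster.items():
        counts: Counter = Counter()
        for name in names:
            tokens = [t for t in re.findall(r"[a-z0-9]+", name.lower()) if t not in stopwords]
            counts.update(set(tokens))
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n_tokens]
        labels[cid] = " ".join(t for t, _ in top) if top else "unnamed"
    return labels


def export_network(network: nx.Graph, clusters: dict | None = None):
    """Edge-list and node tables (TSV-ready DataFrames)."""
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "score": d.get("weight", np.nan)}
            for u, v, d in sorted(network.edges(data=True))
        ],
        columns=["source", "target", "score"],
    )
    nodes = pd.DataFrame(
        [
            {
                "pathway": u,
                "p": d.get("p", np.nan),
                "n_members": d.get("n_members", np.nan),
                "cluster": clusters.get(u) if clusters else None,
            }
            for u, d in sorted(network.nodes(data=True))
        ],
        columns=["pathway", "p", "n_members", "cluster"],
    )
    return edges, nodes
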