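"""Weighted graph metrics for SC matrices.

Edge weights are transformed to connection lengths by ``length = 1/weight``
(the standard convention for streamline-weight connectomes); shortest paths
are computed on the length graph.  Metrics:

* global efficiency  GE = (1/(n(n-1))) * sum_{j != h} 1/d_jh, with
  unreachable pairs contributing 0 (harmonic convention), so GE stays
  defined under severe lesioning;
* mean shortest path length L: mean of d_jh over *reachable* ordered pairs,
  with the number of unreachable ordered pairs reported alongside;
* betweenness centrality BC_j = (1/((n-1)(n-2))) * sum over ordered pairs
  g != h (both != j) of the fraction of shortest g-h paths through j
  (values in [0, 1]);
* clustering coefficient CC_j = 2 t_j / (k_j (k_j - 1)) on the binarized
  (W > 0) graph by default, with a weighted (geometric-mean triangle
  intensity) alternative; nodes of degree < 2 get CC_j = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import ConnectomeMatrix, DegenerateInputError


@dataclass(frozen=True)
class GraphMetricsRecord:
    subject_id: str
    GE: float
    MSPL: float  # nan when no pair is reachable
    mean_BC: float
    mean_CC: float
    n_unreachable_pairs: int


def to_lengths(W: np.ndarray) -> np.ndarray:
    """Connection lengths 1/w (inf where w == 0; diagonal 0)."""
    W = np.asarray(W, dtype=float)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def shortest_paths(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances on a length matrix (Dijkstra)."""
    L = np.asarray(lengths, dtype=float)
    n = L.shape[0]
    finite = np.isfinite(L) & (L > 0)
    graph = csr_array((L[finite], np.nonzero(finite)), shape=(n, n))
    return _csgraph_shortest_path(graph, method="D", directed=False)


def global_efficiency(d: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered pairs."""
    n = d.shape[0]
    if n < 2:
        raise DegenerateInputError("global efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    reach = off & np.isfinite(d) & (d > 0)
    inv[reach] = 1.0 / d[reach]
    return float(inv[off].sum() / (n * (n - 1)))


def char_path_length(d: np.ndarray):
    """Mean shortest path length over reachable ordered pairs.

    Returns ``(L, n_unreachable_pairs)``; L is nan if no pair is reachable.
    """
    n = d.shape[0]
    if n < 2:
        raise DegenerateInputError("path length needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    reach = off & np.isfinite(d)
    n_unreach = int(off.sum() - reach.sum())
    if not reach.any():
        return float("nan"), n_unreach
    return float(d[reach].mean()), n_unreach


def betweenness(lengths: np.ndarray) -> np.ndarray:
    """Normalized betweenness centrality on the length graph.

    Matches the ordered-pair formulation: for undirected graphs the
    normalized Brandes value equals
    (1/((n-1)(n-2))) * sum over ordered (g, h) of rho_gh(j)/rho_gh.
    """
    L = np.asarray(lengths, dtype=float)
    n = L.shape[0]
    if n < 3:
        raise DegenerateInputError("betweenness needs at least 3 nodes")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(np.isfinite(L) & (L > 0), 1))
    G.add_weighted_edges_from(
        (int(i), int(j), float(L[i, j])) for i, j in zip(iu, ju)
    )
    bc = nx.betweenness_centrality(G, weight="weight", normalized=True)
    return np.array([bc[i] for i in range(n)])


def clustering_coefficients(W: np.ndarray, mode: str = "binary") -> np.ndarray:
    """Per-node clustering coefficient.

    ``binary`` (default): CC_j = 2 t_j / (k_j (k_j - 1)) on the W > 0 graph.
    ``weighted``: geometric-mean triangle intensity on weights normalized by
    the maximum weight.  Degree-< 2 nodes score 0 in both modes.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(W, 1))
    if mode == "binary":
        G.add_edges_from((int(i), int(j)) for i, j in zip(iu, ju))
        cc = nx.clustering(G)
    elif mode == "weighted":
        G.add_weighted_edges_from(
            (int(i), int(j), float(W[i, j])) for i, j in zip(iu, ju)
        )
        cc = nx.clustering(G, weight="weight")
    else:
        raise ValueError("mode must be 'binary' or 'weighted'")
    return np.array([cc[i] for i in range(n)])


def compute_metrics(
    cm: ConnectomeMatrix, cc_mode: str = "binary"
) -> GraphMetricsRecord:
    """All metrics for one subject."""
    lengths = to_lengths(cm.W)
    d = shortest_paths(lengths)
    L, n_unreach = char_path_length(d)
    return GraphMetricsRecord(
        subject_id=cm.subject_id,
        GE=global_efficiency(d),
        MSPL=L,
        mean_BC=float(betweenness(lengths).mean()),
        mean_CC=float(clustering_coefficients(cm.W, mode=cc_mode).mean()),
        n_unreachable_pairs=n_unreach,
    )


def metrics_table(population, cc_mode: str = "binary") -> pd.DataFrame:
    rows = [compute_metrics(cm, cc_mode=cc_mode).__dict__ for cm in population]
    return pd.DataFrame(rows)
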