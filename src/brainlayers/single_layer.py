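"""Single-layer node metrics on binarized band networks.

Four per-electrode centrality measures are computed on each thresholded
band network: degree (row sums of the adjacency matrix), eigenvector
centrality (leading eigenvector of the adjacency matrix, non-negative by
Perron-Frobenius, unit Euclidean norm), the k-core number (largest k such
that the node survives iterative peeling of nodes with degree < k), and
PageRank (stationary distribution of a damped random walk on the network).

Thresholded EEG networks are routinely disconnected or bipartite-ish, so
two numerical conventions are fixed here and shared with the multilayer
variants:

* eigenvector centrality is computed on the largest connected component
  (ties broken by the component containing the lowest node index) and set
  to zero elsewhere - the leading eigenvector of a disconnected graph is
  otherwise non-unique;
* PageRank uses damping 0.85 by default (damping = 1 recovers the pure
  neighbor-averaging recursion PR(v) = sum_{u in B_v} PR(u)/d(u), which is
  only guaranteed to converge on connected non-bipartite graphs); rows of
  isolated nodes teleport uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "NodeMetrics",
    "degree",
    "eigenvector_centrality",
    "kcore",
    "pagerank",
    "METRIC_FUNCS",
]

PAGERANK_TOL = 1e-12
PAGERANK_MAXITER = 10_000


@dataclass
class NodeMetrics:
    """Per-electrode values of one graph metric."""

    values: np.ndarray
    metric: str
    band: str | None = None
    class_label: int | None = None
    recording_id: int | None = None
    channel_labels: tuple[str, ...] | None = None


def _adjacency(net) -> np.ndarray:
    a = np.asarray(getattr(net, "adjacency", net), dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    return a


def _meta(net) -> dict:
    return dict(
        band=getattr(net, "band", None),
        class_label=getattr(net, "class_label", None),
        recording_id=getattr(net, "recording_id", None),
        channel_labels=getattr(net, "channel_labels", None),
    )


def degree(net) -> NodeMetrics:
    """Node degree: d(v) = sum_j a_vj."""
    a = _adjacency(net)
    return NodeMetrics(values=a.sum(axis=1), metric="degree", **_meta(net))


def _leading_component_eigvec(a: np.ndarray) -> np.ndarray:
    """Leading eigenvector restricted to the largest connected component."""
    n = a.shape[0]
    if a.sum() == 0:
        raise ValueError("eigenvector centrality undefined on an empty network")
    n_comp, labels = connected_components(sp.csr_matrix(a), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    # argmax takes the first maximal label; labels are assigned in order of
    # node discovery, so ties resolve to the component of the lowest index
    comp = int(np.argmax(sizes))
    idx = np.flatnonzero(labels == comp)
    sub = a[np.ix_(idx, idx)]
    w, v = scipy.linalg.eigh(sub)
    lead = v[:, -1]
    # Perron vector of a connected non-negative matrix: fix the sign
    if lead.sum() < 0:
        lead = -lead
    lead = np.clip(lead, 0.0, None)
    lead = lead / np.linalg.norm(lead)
    out = np.zeros(n)
    out[idx] = lead
    return out


def eigenvector_centrality(net) -> NodeMetrics:
    """Leading-eigenvector centrality, unit Euclidean norm.

    Computed on the largest connected component; nodes outside it get 0.
    """
    a = _adjacency(net)
    return NodeMetrics(
        values=_leading_component_eigvec(a), metric="eigenvector", **_meta(net)
    )


def core_numbers(a: np.ndarray) -> np.ndarray:
    """Core number of every node by iterative minimum-degree peeling."""
    a = np.asarray(a, dtype=bool)
    n = a.shape[0]
    deg = a.sum(axis=1).astype(int)
    alive = np.ones(n, dtype=bool)
    core = np.zeros(n, dtype=int)
    k = 0
    for _ in range(n):
        cand = np.flatnonzero(alive)
        v = cand[np.argmin(deg[cand])]
        k = max(k, int(deg[v]))
        core[v] = k
        alive[v] = False
        nbrs = np.flatnonzero(a[v] & alive)
        deg[nbrs] -= 1
    return core


def kcore(net) -> NodeMetrics:
    """k-core number: largest k whose k-core subgraph still contains the node."""
    a = _adjacency(net)
    return NodeMetrics(
        values=core_numbers(a != 0).astype(float), metric="kcore", **_meta(net)
    )


def pagerank_vector(
    a: np.ndarray,
    damping: float = 0.85,
    tol: float = PAGERANK_TOL,
    max_iter: int = PAGERANK_MAXITER,
) -> np.ndarray:
    """Stationary vector of the damped random walk on a (weighted) graph.

    Solves ``p = damping * W.T p + (1 - damping)/n`` by power iteration,
    where W is the row-normalized adjacency and rows of isolated nodes
    teleport uniformly.  With damping = 1 this is the undamped
    neighbor-averaging recursion.
    """
    if not 0.0 < damping <= 1.0:
        raise ValueError("damping must lie in (0, 1]")
    n = a.shape[0]
    rowsum = a.sum(axis=1)
    W = np.where(rowsum[:, None] > 0, a / np.where(rowsum[:, None] == 0, 1, rowsum[:, None]), 1.0 / n)
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        p_new = damping * (W.T @ p) + (1.0 - damping) / n
        p_new /= p_new.sum()
        if np.abs(p_new - p).sum() < tol:
            return p_new
        p = p_new
    raise RuntimeError(
        f"PageRank power iteration did not converge within {max_iter} "
        f"iterations (damping={damping}); with damping=1 this can happen on "
        "bipartite components - use damping < 1"
    )


def pagerank(net, damping: float = 0.85) -> NodeMetrics:
    """PageRank of every node; values are non-negative and sum to one."""
    a = _adjacency(net)
    return NodeMetrics(
        values=pagerank_vector(a, damping=damping), metric="pagerank", **_meta(net)
    )


METRIC_FUNCS = {
    "degree": degree,
    "eigenvector": eigenvector_centrality,
    "kcore": kcore,
    "pagerank": pagerank,
}
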