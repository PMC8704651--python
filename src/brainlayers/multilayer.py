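"""Supra-adjacency multilayer networks over the electrophysiological bands.

The four binarized band networks of one (recording, class) pair share their
node set (the electrodes), so they form a multiplex network: node-layer
(i, alpha) maps to row ``alpha * n + i`` of an (n*L) x (n*L) supra-adjacency
matrix whose diagonal blocks are the per-band adjacencies and whose
off-diagonal blocks couple each electrode's replicas across every pair of
layers (categorical / all-to-all replica coupling, ``interlayer_weight`` x
identity) - all bands operate simultaneously, so every replica is linked to
every other replica of the same electrode.

Multilayer metrics are the single-layer ones applied to the supra-graph,
aggregated per electrode:

* degree: sum of the node's intra-layer degrees over all layers (interlayer
  replica edges are excluded by construction);
* PageRank: stationary distribution of the damped walk on the supra-graph
  with teleportation uniform over all N*L node-layers, summed over each
  electrode's replicas (so the aggregate still sums to one);
* eigenvector centrality: leading eigenvector of the supra-adjacency (the
  eigentensor), summed over replicas and renormalized to unit norm;
* k-core: coreness by iterative peeling of the full supra-graph, interlayer
  edges included, maximum over replicas.  The coreness distribution
  P_k = n_k / |k-core| is available as a diagnostic table.

With a single layer every metric reduces exactly to its single-layer
counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .single_layer import (
    NodeMetrics,
    _adjacency,
    _leading_component_eigvec,
    core_numbers,
    pagerank_vector,
)

__all__ = [
    "SupraAdjacency",
    "build_supra",
    "ml_degree",
    "ml_pagerank",
    "ml_eigenvector",
    "ml_kcore",
    "kcore_distribution",
    "extended_edge_list",
]


@dataclass
class SupraAdjacency:
    """Block supra-adjacency matrix of a multiplex network."""

    matrix: np.ndarray  # (n*L, n*L)
    n: int
    L: int
    layer_order: tuple[str, ...]
    interlayer_weight: float = 1.0
    class_label: int | None = None
    recording_id: int | None = None
    channel_labels: tuple[str, ...] | None = None

    def intra_block(self, layer: int) -> np.ndarray:
        s = slice(layer * self.n, (layer + 1) * self.n)
        return self.matrix[s, s]


def build_supra(
    networks: Sequence,
    interlayer_weight: float = 1.0,
    *,
    class_label: int | None = None,
    recording_id: int | None = None,
) -> SupraAdjacency:
    """Assemble the supra-adjacency matrix from per-band binary networks.

    All networks must share the electrode ordering; replica coupling is
    all-to-all across layer pairs with the given weight.
    """
    mats = [_adjacency(net) for net in networks]
    n = mats[0].shape[0]
    labels = [getattr(net, "channel_labels", None) for net in networks]
    ref = labels[0]
    for m, lab in zip(mats, labels):
        if m.shape[0] != n:
            raise ValueError("layers disagree on the number of electrodes")
        if ref is not None and lab is not None and tuple(lab) != tuple(ref):
            raise ValueError("layers disagree on the electrode ordering")
    L = len(mats)
    supra = np.zeros((n * L, n * L))
    eye = np.eye(n)
    for a in range(L):
        sa = slice(a * n, (a + 1) * n)
        supra[sa, sa] = mats[a]
        for b in range(a + 1, L):
            sb = slice(b * n, (b + 1) * n)
            supra[sa, sb] = interlayer_weight * eye
            supra[sb, sa] = interlayer_weight * eye
    bands = tuple(
        getattr(net, "band", None) or f"layer{k}" for k, net in enumerate(networks)
    )
    cls = class_label if class_label is not None else getattr(networks[0], "class_label", None)
    rid = recording_id if recording_id is not None else getattr(networks[0], "recording_id", None)
    return SupraAdjacency(
        matrix=supra,
        n=n,
        L=L,
        layer_order=bands,
        interlayer_weight=interlayer_weight,
        class_label=cls,
        recording_id=rid,
        channel_labels=tuple(ref) if ref is not None else None,
    )


def _meta(supra: SupraAdjacency) -> dict:
    return dict(
        band="multilayer",
        class_label=supra.class_label,
        recording_id=supra.recording_id,
        channel_labels=supra.channel_labels,
    )


def _aggregate_sum(values: np.ndarray, n: int, L: int) -> np.ndarray:
    return values.reshape(L, n).sum(axis=0)


def ml_degree(supra: SupraAdjacency) -> NodeMetrics:
    """Sum of a node's intra-layer degrees across layers (replica edges excluded)."""
    vals = np.zeros(supra.n)
    for a in range(supra.L):
        vals += supra.intra_block(a).sum(axis=1)
    return NodeMetrics(values=vals, metric="degree", **_meta(supra))


def ml_pagerank(supra: SupraAdjacency, r: float = 0.85) -> NodeMetrics:
    """Damped supra-walk PageRank, summed over each electrode's replicas."""
    p = pagerank_vector(supra.matrix, damping=r)
    return NodeMetrics(
        values=_aggregate_sum(p, supra.n, supra.L), metric="pagerank", **_meta(supra)
    )


def ml_eigenvector(supra: SupraAdjacency) -> NodeMetrics:
    """Leading supra-eigenvector summed over replicas, renormalized to unit norm."""
    theta = _leading_component_eigvec(supra.matrix)
    agg = _aggregate_sum(theta, supra.n, supra.L)
    norm = np.linalg.norm(agg)
    if norm > 0:
        agg = agg / norm
    return NodeMetrics(values=agg, metric="eigenvector", **_meta(supra))


def ml_kcore(supra: SupraAdjacency) -> NodeMetrics:
    """Supra-graph coreness (interlayer edges included), max over replicas."""
    m = supra.matrix
    if supra.interlayer_weight not in (0.0, 1.0) or not np.isin(m, (0, 1)).all():
        warnings.warn(
            "k-core requires integer degrees; using the unweighted supra-graph "
            "(any non-zero weight counts as an edge)"
        )
    core = core_numbers(m != 0)
    vals = core.reshape(supra.L, supra.n).max(axis=0).astype(float)
    return NodeMetrics(values=vals, metric="kcore", **_meta(supra))


def extended_edge_list(supra: SupraAdjacency) -> pd.DataFrame:
    """Edges as (node_i, layer_i, node_j, layer_j, weight) rows."""
    labels = supra.channel_labels or tuple(f"ch{i}" for i in range(supra.n))
    rows, cols = np.nonzero(np.triu(supra.matrix, 1))
    recs = []
    for r, c in zip(rows, cols):
        recs.append(
            {
                "node_i": labels[r % supra.n],
                "layer_i": supra.layer_order[r // supra.n],
                "node_j": labels[c % supra.n],
                "layer_j": supra.layer_order[c // supra.n],
                "weight": supra.matrix[r, c],
            }
        )
    return pd.DataFrame(recs)


def kcore_distribution(supra: SupraAdjacency) -> pd.DataFrame:
    """Diagnostic coreness distribution of the supra-graph.

    For each coreness level k: ``n_k`` node-layers have core number exactly
    k, the k-core contains ``kcore_size`` node-layers, and ``P`` = n_k /
    kcore_size is the fraction of the k-core sitting exactly at level k.
    """
    core = core_numbers(supra.matrix != 0)
    rows = []
    for k in np.unique(core):
        size = int((core >= k).sum())
        nk = int((core == k).sum())
        rows.append({"k": int(k), "n_k": nk, "kcore_size": size, "P": nk / size})
    return pd.DataFrame(rows)
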