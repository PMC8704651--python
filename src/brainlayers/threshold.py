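"""Binarization of weighted adjacency matrices: fixed (mean) and Otsu thresholds.

Functional connectivity yields a continuum of edge weights; thresholding
separates effective from spurious connections before graph analysis.  Two
rules are implemented:

* **fixed**: the threshold is the arithmetic mean of all matrix entries -
  the classical choice, sensitive to outliers and skewed weight
  distributions;
* **otsu**: the histogram-based rule from image segmentation, adapted to
  adjacency matrices.  For a candidate threshold T the entries split into
  class C1 (weights < T, spurious) and C2 (weights >= T, effective) with
  occupancies w1, w2, means mu1, mu2 and variances s1^2, s2^2; the
  within-class variance WCV = w1 s1^2 + w2 s2^2 and the between-class
  variance BCV = w1 w2 (mu1 - mu2)^2 satisfy WCV + BCV = total variance, so
  maximizing BCV and minimizing WCV pick the same optimum.

Conventions, fixed once: all n*n entries including the unit self-coherence
diagonal enter the histogram and the mean (N = 22 x 22 in the reference
montage); class assignment at the boundary puts entries < T into C1;
binarization keeps edges with weight strictly greater than T and always
removes self-loops.  Candidate thresholds are the midpoints between
consecutive distinct entry values, which reproduces an exhaustive sweep
exactly without an arbitrary step size; among equally optimal candidates the
smallest (most edge-retaining) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThresholdResult",
    "BinaryNetwork",
    "fixed_threshold",
    "otsu_threshold",
    "binarize",
    "curves_frame",
    "edge_list",
]


@dataclass
class ThresholdResult:
    """A chosen threshold with (for Otsu) its WCV/BCV diagnostics."""

    T: float
    method: str  # "fixed" or "otsu"
    candidates: np.ndarray | None = None
    wcv_curve: np.ndarray | None = None
    bcv_curve: np.ndarray | None = None


@dataclass
class BinaryNetwork:
    """A binarized symmetric network without self-loops."""

    adjacency: np.ndarray  # (n, n) in {0, 1}
    threshold: ThresholdResult
    band: str | None = None
    class_label: int | None = None
    recording_id: int | None = None
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def _entries(layer) -> np.ndarray:
    m = np.asarray(getattr(layer, "matrix", layer), dtype=float)
    if m.size == 0:
        raise ValueError("empty adjacency matrix")
    return m


def fixed_threshold(layer) -> ThresholdResult:
    """Mean of all matrix entries, diagonal included (same N as Otsu)."""
    m = _entries(layer)
    return ThresholdResult(T=float(m.mean()), method="fixed")


def otsu_threshold(layer) -> ThresholdResult:
    """Adaptive threshold maximizing the between-class variance.

    Every midpoint between consecutive distinct entry values is evaluated;
    for each candidate the split statistics use population (ddof=0)
    variances, so WCV + BCV equals the total entry variance identically.

    Raises
    ------
    ValueError
        If all entries are identical (no two classes to separate).
    """
    m = _entries(layer)
    v = np.sort(m.ravel())
    n = v.size
    uniq, first = np.unique(v, return_index=True)
    if uniq.size < 2:
        raise ValueError(
            "all adjacency entries are identical; Otsu's threshold needs at "
            "least two distinct values to separate"
        )
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    n1 = first[1:].astype(float)  # |C1| for each candidate
    n2 = n - n1
    cs = np.cumsum(v)
    cs2 = np.cumsum(v * v)
    s1 = cs[first[1:] - 1]
    q1 = cs2[first[1:] - 1]
    mu1 = s1 / n1
    mu2 = (cs[-1] - s1) / n2
    var1 = np.maximum(q1 / n1 - mu1**2, 0.0)
    var2 = np.maximum((cs2[-1] - q1) / n2 - mu2**2, 0.0)
    w1 = n1 / n
    w2 = n2 / n
    wcv = w1 * var1 + w2 * var2
    bcv = w1 * w2 * (mu1 - mu2) ** 2
    best = int(np.argmax(bcv))  # first occurrence = smallest optimal T
    return ThresholdResult(
        T=float(candidates[best]),
        method="otsu",
        candidates=candidates,
        wcv_curve=wcv,
        bcv_curve=bcv,
    )


def curves_frame(result: ThresholdResult):
    """WCV/BCV diagnostic curves as a TSV-friendly DataFrame (Otsu only)."""
    import pandas as pd

    if result.candidates is None:
        raise ValueError(f"no candidate curves on a {result.method!r} result")
    return pd.DataFrame(
        {"T": result.candidates, "WCV": result.wcv_curve, "BCV": result.bcv_curve}
    )


def edge_list(net: "BinaryNetwork") -> list[tuple[str, str]]:
    """Edges as (electrode_i, electrode_j) name pairs, i < j."""
    labels = net.channel_labels or tuple(f"ch{i}" for i in range(net.n_nodes))
    rows, cols = np.nonzero(np.triu(net.adjacency, 1))
    return [(labels[i], labels[j]) for i, j in zip(rows, cols)]


def binarize(layer, result: ThresholdResult) -> BinaryNetwork:
    """Keep edges with weight strictly above the threshold; drop self-loops."""
    m = _entries(layer)
    a = (m > result.T).astype(np.int8)
    a = np.minimum(a, a.T)  # weighted input is symmetric; keep it exact
    np.fill_diagonal(a, 0)
    return BinaryNetwork(
        adjacency=a,
        threshold=result,
        band=getattr(layer, "band", None),
        class_label=getattr(layer, "class_label", None),
        recording_id=getattr(layer, "recording_id", None),
        channel_labels=getattr(layer, "channel_labels", None),
    )
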