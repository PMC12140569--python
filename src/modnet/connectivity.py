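"""Connectivity matrices and relative-threshold binary graphs.

Pearson correlation over retained volumes, optional partial correlation
controlling for the global signal, the global-FC summary (mean of all
off-diagonal correlations), and proportional thresholding: the top
fraction of correlations becomes the edge set of an undirected, unweighted
graph. Ranking is by signed correlation by default (a strongly negative
correlation is not a strong edge), switchable to magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import TimeSeries


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    threshold_proportion: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def pearson_matrix(ts: TimeSeries, meta: dict | None = None) -> np.ndarray:
    """Node-by-node Pearson correlation over retained volumes."""
    X = ts.retained()
    if X.shape[1] < 3:
        raise ValueError("need at least 3 retained volumes")
    sd = X.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node(s) on retained volumes: {dead.tolist()}")
    C = np.corrcoef(X)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return C


def partial_corr_global(ts: TimeSeries, global_signal: np.ndarray) -> np.ndarray:
    """Pairwise correlations with the global signal partialled out.

    r_ij.g = (r_ij - r_ig r_jg) / sqrt((1 - r_ig^2)(1 - r_jg^2)); equivalent
    to correlating the OLS residuals of each node on the global signal.
    """
    g = np.asarray(global_signal, dtype=float).ravel()
    if g.size != ts.n_volumes:
        raise ValueError("global signal length must match the number of volumes")
    g = g[ts.volume_mask]
    if g.std() == 0:
        raise ValueError("global signal is constant on retained volumes")
    C = pearson_matrix(ts)
    X = ts.retained()
    gz = (g - g.mean()) / g.std()
    xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    rg = xz @ gz / g.size
    if np.any(np.abs(rg) >= 1.0 - 1e-12):
        bad = np.flatnonzero(np.abs(rg) >= 1.0 - 1e-12)
        raise ValueError(f"node(s) {bad.tolist()} are collinear with the global signal")
    denom = np.sqrt(np.outer(1.0 - rg**2, 1.0 - rg**2))
    P = (C - np.outer(rg, rg)) / denom
    np.fill_diagonal(P, 1.0)
    return np.clip((P + P.T) / 2.0, -1.0, 1.0)


def global_fc(corr: np.ndarray) -> float:
    """Mean of the off-diagonal (upper-triangle) correlations."""
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(corr[iu].mean())


def _edge_count(n: int, proportion: float) -> int:
    """round-half-away-from-zero(proportion * n(n-1)/2)."""
    m = n * (n - 1) // 2
    return int(np.floor(proportion * m + 0.5))


def relative_threshold(corr: np.ndarray, proportion: float,
                       rank: str = "signed", meta: dict | None = None) -> BinaryGraph:
    """Binarize by keeping the top ``proportion`` of node pairs as edges.

    Pairs are ranked by signed correlation (``rank='signed'``, default) or
    by magnitude (``rank='abs'``); ties at the cut are broken by (i, j)
    lexicographic order, so the result is deterministic and edge sets are
    nested across proportions.
    """
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must be in (0, 1)")
    if rank not in ("signed", "abs"):
        raise ValueError("rank must be 'signed' or 'abs'")
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    if rank == "abs":
        vals = np.abs(vals)
    # primary: value descending; ties: i then j ascending
    order = np.lexsort((ju, iu, -vals))
    k = _edge_count(n, proportion)
    A = np.zeros((n, n), dtype=np.uint8)
    sel = order[:k]
    A[iu[sel], ju[sel]] = 1
    A |= A.T
    m = dict(meta or {})
    m.update(threshold_proportion=proportion, rank=rank)
    return BinaryGraph(A, proportion, m)
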