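"""Binary graph metrics and the module-level local/global aggregation.

All node metrics operate on undirected, unweighted graphs and are
implemented directly (BFS geodesics, Brandes betweenness, power-iteration
eigenvector centrality) rather than delegated, so every convention —
disconnected-pair handling, normalization, isolated nodes — is explicit:

* geodesic means exclude unreachable pairs; a fully isolated node has an
  undefined path length and is dropped from module averages with a warning;
* nodal efficiency uses 1/inf = 0, so isolated nodes score 0;
* betweenness is reported unnormalized (raw pair-dependency sums, each
  unordered pair counted once), with an optional (n-1)(n-2)/2 normalization;
* eigenvector centrality lives on the largest connected component, zero
  elsewhere.

The two aggregation modes mirror how a functional module can be read:
*local* metrics are computed on the subgraph induced by the module's nodes
(within-module integration), *global* metrics on the whole-brain graph and
then averaged over the module's nodes (the module's integration with
everything else). Assortativity is local-only; participation coefficient is
global-only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .connectivity import BinaryGraph

LOCAL_ONLY = {"assortativity"}
GLOBAL_ONLY = {"participation_coefficient"}
NODE_METRICS = (
    "degree_density",
    "shortest_path_length",
    "clustering_coefficient",
    "nodal_efficiency",
    "betweenness_centrality",
    "eigenvector_centrality",
)
ALL_METRICS = NODE_METRICS + ("assortativity", "participation_coefficient")


def _adj(g) -> np.ndarray:
    return g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g, dtype=np.uint8)


# ---------------------------------------------------------------------------
# node metrics
# ---------------------------------------------------------------------------

def degree_density(g) -> np.ndarray:
    """Per-node degree scaled by n-1; the module mean equals graph density."""
    A = _adj(g)
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return A.sum(axis=1) / (n - 1)


def distance_matrix(g) -> np.ndarray:
    """All-pairs unit-edge geodesic distances (np.inf for unreachable)."""
    A = _adj(g).astype(bool)
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        nxt = (frontier.astype(np.int64) @ A.astype(np.int64) > 0) & ~reached
        D[nxt] = d
        reached |= nxt
        frontier = nxt
    return D


def shortest_path_lengths(g) -> np.ndarray:
    """Per-node mean geodesic distance to reachable others; NaN if isolated."""
    D = distance_matrix(g)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    out = np.empty(n)
    for i in range(n):
        finite = np.isfinite(D[i]) & (np.arange(n) != i)
        out[i] = D[i, finite].mean() if finite.any() else np.nan
    return out


def clustering_coefficient(g) -> np.ndarray:
    """Fraction of a node's neighbor pairs that are themselves connected."""
    A = _adj(g).astype(np.int64)
    k = A.sum(axis=1)
    tri = np.diag(A @ A @ A) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 2.0 * tri / (k * (k - 1))
    c[k < 2] = 0.0
    return c


def nodal_efficiency(g) -> np.ndarray:
    """Per-node mean inverse geodesic distance (1/inf = 0)."""
    D = distance_matrix(g)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(D)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def betweenness_centrality(g, normalized: bool = False) -> np.ndarray:
    """Brandes accumulation of shortest-path pair-dependencies.

    Unnormalized by default: node value = number of geodesics through it,
    fractional for ties, each unordered pair counted once.
    """
    A = _adj(g)
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    nbrs = [np.flatnonzero(A[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        while queue:
            v = queue.pop(0)
            stack.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair visited from both endpoints
    if normalized:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def connected_components(g) -> list[np.ndarray]:
    """Node-index arrays of the connected components, largest first."""
    D = distance_matrix(g)
    n = D.shape[0]
    unseen = np.ones(n, dtype=bool)
    comps = []
    for i in range(n):
        if unseen[i]:
            comp = np.flatnonzero(np.isfinite(D[i]))
            comps.append(comp)
            unseen[comp] = False
    return sorted(comps, key=len, reverse=True)


def eigenvector_centrality(g, tol: float = 1e-10, max_iter: int = 10000) -> np.ndarray:
    """Nonnegative leading eigenvector of the largest component's adjacency.

    Power iteration on A + I (same eigenvectors, strictly dominant leading
    eigenvalue, so bipartite components converge too); unit Euclidean norm;
    nodes outside the largest component get 0.
    """
    A = _adj(g).astype(float)
    n = A.shape[0]
    if A.sum() == 0:
        raise ValueError("graph has no edges")
    comp = connected_components(A)[0]
    B = A[np.ix_(comp, comp)] + np.eye(len(comp))
    v = np.ones(len(comp)) / np.sqrt(len(comp))
    for _ in range(max_iter):
        w = B @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    out = np.zeros(n)
    out[comp] = np.abs(v)
    return out


def assortativity(g) -> float:
    """Degree correlation over edge endpoints (both orientations).

    NaN (undefined) when endpoint degrees have zero variance, e.g. on a
    regular graph.
    """
    A = _adj(g)
    k = A.sum(axis=1).astype(float)
    iu, ju = np.nonzero(np.triu(A, k=1))
    if iu.size < 2:
        raise ValueError("need at least 2 edges")
    x = np.concatenate([k[iu], k[ju]])
    y = np.concatenate([k[ju], k[iu]])
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def participation_coefficient(g, community: np.ndarray) -> np.ndarray:
    """1 - sum over communities of (within-community degree fraction)^2."""
    A = _adj(g).astype(float)
    n = A.shape[0]
    community = np.asarray(community)
    if community.shape != (n,):
        raise ValueError("community labels must cover every node")
    k = A.sum(axis=1)
    pc = np.ones(n)
    for c in np.unique(community):
        kc = A[:, community == c].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pc -= (kc / k) ** 2
    pc[k == 0] = 0.0
    return pc


# ---------------------------------------------------------------------------
# module aggregation
# ---------------------------------------------------------------------------

def modules_from_assignment(assignment: pd.DataFrame, node_ids: np.ndarray,
                            level: int) -> dict[str, np.ndarray]:
    """Map module name -> graph-index array for one hierarchy level.

    ``node_ids`` gives, per graph index, the node_id it carries (the row
    order of the connectivity matrix). Level-2 sets are unpacked so a node
    can appear in two modules.
    """
    from .atlas import NONE_LABEL

    pos = {nid: i for i, nid in enumerate(node_ids)}
    col = f"level{level}"
    out: dict[str, list[int]] = {}
    for nid, cell in zip(assignment["node_id"], assignment[col]):
        if cell == NONE_LABEL or nid not in pos:
            continue
        for name in (cell.split(";") if level == 2 else [cell]):
            out.setdefault(name, []).append(pos[nid])
    return {k: np.array(sorted(v)) for k, v in sorted(out.items())}


def community_labels(modules: dict[str, np.ndarray], n_nodes: int) -> np.ndarray:
    """Community partition for the participation coefficient: one community
    per module plus a catch-all for unassigned nodes (index 0). Nodes in
    several modules take the first (name-sorted) one."""
    labels = np.zeros(n_nodes, dtype=int)
    for c, (_, idx) in enumerate(sorted(modules.items()), start=1):
        labels[idx[labels[idx] == 0]] = c
    return labels


def _node_metric(metric: str, g, community: np.ndarray | None):
    if metric == "degree_density":
        return degree_density(g)
    if metric == "shortest_path_length":
        return shortest_path_lengths(g)
    if metric == "clustering_coefficient":
        return clustering_coefficient(g)
    if metric == "nodal_efficiency":
        return nodal_efficiency(g)
    if metric == "betweenness_centrality":
        return betweenness_centrality(g)
    if metric == "eigenvector_centrality":
        return eigenvector_centrality(g)
    if metric == "participation_coefficient":
        if community is None:
            raise ValueError("participation coefficient needs a community partition")
        return participation_coefficient(g, community)
    raise ValueError(f"unknown metric {metric!r}")


def module_metrics(g, modules: dict[str, np.ndarray], mode: str,
                   metrics=ALL_METRICS, community: np.ndarray | None = None,
                   subject=None, task=None, level=None) -> pd.DataFrame:
    """Module-level metric table for one binary graph.

    ``modules`` maps module name to graph-index array. In ``local`` mode the
    metric is computed on the module-induced subgraph and averaged over its
    nodes; in ``global`` mode on the full graph, averaged over module nodes.
    Too-small modules yield a NaN row with a warning rather than an error.
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    A = _adj(g)
    metrics = [m for m in metrics
               if not (mode == "local" and m in GLOBAL_ONLY)
               and not (mode == "global" and m in LOCAL_ONLY)]
    if community is None and mode == "global" and "participation_coefficient" in metrics:
        community = community_labels(modules, A.shape[0])

    cache: dict[str, np.ndarray] = {}
    rows = []
    for name, idx in modules.items():
        for metric in metrics:
            value = np.nan
            if mode == "global":
                if metric not in cache:
                    cache[metric] = _node_metric(metric, A, community)
                vals = cache[metric][idx]
                value = _nanmean_warn(vals, name, metric)
            else:
                min_n = 3 if metric == "betweenness_centrality" else 2
                if len(idx) < min_n:
                    warnings.warn(f"module {name!r}: too few nodes for local {metric}",
                                  stacklevel=2)
                elif metric == "assortativity":
                    sub = A[np.ix_(idx, idx)]
                    value = assortativity(sub) if np.triu(sub, 1).sum() >= 2 else np.nan
                else:
                    vals = _node_metric(metric, A[np.ix_(idx, idx)], None)
                    value = _nanmean_warn(vals, name, metric)
            rows.append({"subject": subject, "task": task, "module": name,
                         "level": level, "mode": mode, "metric": metric,
                         "value": value, "n_module_nodes": len(idx)})
    return pd.DataFrame(rows)


def _nanmean_warn(vals: np.ndarray, module: str, metric: str) -> float:
    vals = np.asarray(vals, dtype=float)
    if np.isnan(vals).any():
        warnings.warn(f"module {module!r}: {int(np.isnan(vals).sum())} node(s) "
                      f"excluded from {metric} mean (undefined)", stacklevel=3)
    if np.isnan(vals).all():
        return float("nan")
    return float(np.nanmean(vals))
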