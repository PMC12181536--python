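"""Lineage inference through the embedding: a minimum spanning tree over
cluster centroids rooted at the healthy cluster, simultaneous principal
curves along each root-to-leaf path, per-cell pseudotime and lineage weights,
and truncation of trajectories that drift backwards in experimental time.

This is a cluster-graph trajectory construction in the Slingshot family: the
tree fixes the lineage topology, and each lineage's curve is refined by
iterating {project member cells onto the curve -> smooth each coordinate
against arc length -> reparameterize by arc length}.  Pseudotime is the
arc-length position of a cell's projection; cells in clusters shared by
several lineages receive inverse-squared-distance membership weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LineageSet",
    "build_mst",
    "extract_lineages",
    "fit_principal_curves",
    "truncate_backward",
    "infer_lineages",
]


def build_mst(centroids: np.ndarray) -> nx.Graph:
    """Minimum spanning tree over centroids under Euclidean distance.

    Kruskal with edges sorted by (weight, u, v), so ties break
    lexicographically and the tree is deterministic.  Duplicate centroids
    yield a valid zero-weight edge (warned).
    """
    centroids = np.asarray(centroids, dtype=float)
    n = centroids.shape[0]
    if n < 2:
        raise ValueError("need at least 2 centroids")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            w = float(np.linalg.norm(centroids[i] - centroids[j]))
            edges.append((w, i, j))
    if any(w == 0.0 for w, _, _ in edges):
        warnings.warn("duplicate centroids: zero-weight MST edge", stacklevel=2)
    edges.sort()

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = nx.Graph()
    tree.add_nodes_from(range(n))
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.add_edge(i, j, weight=w)
            if tree.number_of_edges() == n - 1:
                break
    return tree


def extract_lineages(tree: nx.Graph, root: int) -> List[List[int]]:
    """One ordered cluster path per leaf, each the unique root-to-leaf path."""
    if root not in tree:
        raise ValueError(f"root {root} not in tree")
    leaves = [v for v in tree.nodes if tree.degree(v) == 1 and v != root]
    if not leaves:                       # single-node or root-only tree
        return [[root]]
    return [nx.shortest_path(tree, root, leaf) for leaf in sorted(leaves)]


def _project_on_polyline(points: np.ndarray,
                         curve: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project points onto a piecewise-linear curve.

    Returns (arc_length, distance, projected_points).
    """
    seg_vec = np.diff(curve, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_len = np.maximum(seg_len, 1e-300)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    best_d = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    best_p = np.zeros_like(points)
    for k in range(len(seg_vec)):
        a, v, L = curve[k], seg_vec[k], seg_len[k]
        t = np.clip(((points - a) @ v) / (L * L), 0.0, 1.0)
        proj = a + t[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_s[better] = cum[k] + t[better] * L
        best_p[better] = proj[better]
    return best_s, best_d, best_p


def _smooth_curve(points: np.ndarray, s: np.ndarray, grid_n: int,
                  span: float) -> np.ndarray:
    """Lowess-smooth each coordinate against arc length on a uniform grid."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    grid = np.linspace(s.min(), s.max(), grid_n)
    out = np.empty((grid_n, points.shape[1]))
    for d in range(points.shape[1]):
        out[:, d] = lowess(points[:, d], s, frac=span, it=0, xvals=grid,
                           delta=0.0)
    return out


@dataclass
class LineageSet:
    """Rooted lineage structure with curves, pseudotime and truncations."""

    tree: nx.Graph
    root: int
    lineages: List[List[int]]                      # ordered cluster paths
    curves: List[np.ndarray] = field(default_factory=list)
    cell_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    truncations: Dict[int, Optional[float]] = field(default_factory=dict)
    converged: List[bool] = field(default_factory=list)
    n_iter: List[int] = field(default_factory=list)

    def members(self, lineage: int, truncated: bool = True) -> pd.DataFrame:
        """Rows of the cell table for one lineage, dropping cells beyond the
        truncation point when ``truncated``."""
        sub = self.cell_table[self.cell_table["lineage"] == lineage]
        tau = self.truncations.get(lineage)
        if truncated and tau is not None:
            sub = sub[sub["pseudotime"] <= tau]
        return sub

    def length(self, lineage: int, truncated: bool = True) -> float:
        tau = self.truncations.get(lineage)
        full = float(self.cell_table.loc[
            self.cell_table["lineage"] == lineage, "pseudotime"].max())
        if truncated and tau is not None:
            return min(tau, full)
        return full


def fit_principal_curves(
    coords: np.ndarray,
    cluster_labels: np.ndarray,
    lineages: List[List[int]],
    centroids: Optional[np.ndarray] = None,
    tol: float = 1e-3,
    max_iter: int = 50,
    span: float = 0.6,
    grid_n: int = 100,
) -> Tuple[List[np.ndarray], pd.DataFrame, List[bool], List[int]]:
    """Fit one principal curve per lineage and assign pseudotime/weights.

    Each curve starts as the piecewise-linear path through the lineage's
    cluster centroids (computed from ``coords`` when not given) and is
    iterated to a fixed point of projection + lowess smoothing.  Returns
    (curves, cell_table, converged_flags, iteration_counts); the cell table
    has columns {index, lineage, pseudotime, weight, dist}.
    """
    coords = np.asarray(coords, dtype=float)
    if centroids is None:
        ks = int(cluster_labels.max()) + 1
        centroids = np.vstack([
            coords[cluster_labels == c].mean(axis=0) if (cluster_labels == c).any()
            else np.zeros(coords.shape[1]) for c in range(ks)])

    curves, conv, iters = [], [], []
    rows: List[pd.DataFrame] = []
    member_dists: Dict[int, Dict[int, np.ndarray]] = {}  # lineage -> idx -> (s, d)

    for li, path in enumerate(lineages):
        member = np.flatnonzero(np.isin(cluster_labels, path))
        pts = coords[member]
        control = _extend_ends(centroids[path], pts,
                               cluster_labels[member], path)
        curve = _densify(control, grid_n)
        converged, it = False, 0
        for it in range(1, max_iter + 1):
            s, d, _ = _project_on_polyline(pts, curve)
            if np.ptp(s) == 0:           # degenerate: all projections coincide
                break
            new_curve = _smooth_curve(pts, s, grid_n, span)
            move = float(np.mean(np.linalg.norm(new_curve - curve, axis=1)))
            scale = max(float(np.ptp(s)), 1e-12)
            curve = new_curve
            if move < tol * scale:
                converged = True
                break
        s, d, _ = _project_on_polyline(pts, curve)
        curves.append(curve)
        conv.append(converged)
        iters.append(it)
        rows.append(pd.DataFrame({"index": member, "lineage": li,
                                  "pseudotime": s, "dist": d}))

    table = pd.concat(rows, ignore_index=True)
    # inverse-squared-distance weights over the lineages sharing each cell
    w = np.empty(len(table))
    inv2 = 1.0 / (table["dist"].to_numpy() ** 2 + 1e-12)
    table["_inv2"] = inv2
    denom = table.groupby("index")["_inv2"].transform("sum")
    table["weight"] = table["_inv2"] / denom
    table = table.drop(columns="_inv2")
    return curves, table, conv, iters


def _extend_ends(control: np.ndarray, pts: np.ndarray,
                 member_clusters: np.ndarray, path: Sequence[int]) -> np.ndarray:
    """Extend the centroid polyline past both end centroids so it spans the
    member cells; otherwise cells beyond an end centroid all clamp onto the
    curve tip and collapse to a single pseudotime."""
    if len(control) < 2:
        return control
    out = control.copy()
    for endpoint, neighbor, cluster, pos in (
            (0, 1, path[0], "start"), (-1, -2, path[-1], "end")):
        direction = control[endpoint] - control[neighbor]
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        direction = direction / norm
        own = pts[member_clusters == cluster]
        if len(own) == 0:
            continue
        reach = float(((own - control[endpoint]) @ direction).max())
        if reach > 0:
            tip = control[endpoint] + direction * reach
            out = np.vstack([tip, out]) if pos == "start" else np.vstack([out, tip])
    return out


def _densify(control: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline through control points to ``n`` arc-length-uniform
    vertices."""
    seg = np.linalg.norm(np.diff(control, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return np.repeat(control[:1], n, axis=0)
    grid = np.linspace(0, cum[-1], n)
    out = np.empty((n, control.shape[1]))
    for d in range(control.shape[1]):
        out[:, d] = np.interp(grid, cum, control[:, d])
    return out


def truncate_backward(
    pseudotime: np.ndarray,
    cell_days: np.ndarray,
    window: Optional[int] = None,
    slack: float = 0.5,
) -> Optional[float]:
    """Truncation point of a lineage that starts moving backwards in
    experimental time.

    The mean experimental day is smoothed along pseudotime by a running mean
    (window defaults to 5% of the cells, at least 25).  If, beyond the
    running peak of that curve, the smoothed day falls by more than
    ``slack`` days, the lineage is truncated at the pseudotime of the peak;
    otherwise no truncation.  Returns the truncation pseudotime or ``None``.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    cell_days = np.asarray(cell_days, dtype=float)
    n = len(pseudotime)
    if window is None:
        window = max(25, int(np.ceil(0.05 * n)))
    if n < window:
        warnings.warn(f"fewer cells ({n}) than window ({window}); no truncation",
                      stacklevel=2)
        return None
    order = np.argsort(pseudotime, kind="stable")
    pt = pseudotime[order]
    day = cell_days[order]
    smooth = pd.Series(day).rolling(window, center=True, min_periods=1).mean().to_numpy()

    # truncate only when the smoothed day falls below its global peak by
    # more than the slack somewhere beyond the peak; a first-crossing rule
    # would fire on ordinary windowed-mean noise near the start
    peak_idx = int(np.argmax(smooth))
    if peak_idx < n - 1 and smooth[peak_idx:].min() < smooth[peak_idx] - slack:
        return float(pt[peak_idx])
    return None


def infer_lineages(
    coords: np.ndarray,
    cluster_labels: np.ndarray,
    root: int,
    cell_days: Optional[np.ndarray] = None,
    truncate: bool = True,
    slack: float = 0.5,
    **curve_kwargs,
) -> LineageSet:
    """Full lineage inference: centroid MST, root-to-leaf paths, principal
    curves, pseudotime, and (optionally) backward-time truncation."""
    ks = int(cluster_labels.max()) + 1
    centroids = np.vstack([
        coords[cluster_labels == c].mean(axis=0) for c in range(ks)])
    tree = build_mst(centroids)
    lineages = extract_lineages(tree, root)
    curves, table, conv, iters = fit_principal_curves(
        coords, cluster_labels, lineages, centroids=centroids, **curve_kwargs)
    ls = LineageSet(tree=tree, root=root, lineages=lineages, curves=curves,
                    cell_table=table, converged=conv, n_iter=iters)
    if truncate and cell_days is not None:
        for li in range(len(lineages)):
            sub = table[table["lineage"] == li]
            ls.truncations[li] = truncate_backward(
                sub["pseudotime"].to_numpy(),
                np.asarray(cell_days)[sub["index"].to_numpy()],
                slack=slack)
    else:
        ls.truncations = {li: None for li in range(len(lineages))}
    return ls
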