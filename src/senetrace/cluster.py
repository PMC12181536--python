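"""Subpopulation discovery: k-means with control-anchored cluster-count
selection, cluster-to-role mapping, and composition over time.

The cluster count is chosen to maximize how well the untreated (day-0)
control cells concentrate in a single cluster.  The raw criterion —
"percentage of control cells in one cluster" — is maximal at k=1, so the
default score is recall x purity of the best cluster: recall is the fraction
of all control cells captured, purity the fraction of that cluster that is
control.  The literal recall-only reading is available via ``score='recall'``.

Role mapping turns the k clusters into six biological roles (healthy, two
transitional, three terminal) by explicit deterministic rules in place of
manual cluster sorting: the healthy cluster anchors the
map, terminal clusters are distant from healthy and peak late in the time
course, and clusters on the centroid-tree path from healthy to a senescent
terminal are senescent-transitional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic import (
    HEALTHY,
    HIGH_CONCENTRATION,
    LARGE_NUCLEAR,
    NONSENESCENT_TERMINAL,
    NONSENESCENT_TRANSITIONAL,
    ROLES,
    SENESCENCE_MARKERS,
    SENESCENT_TRANSITIONAL,
)

__all__ = [
    "SubpopulationModel",
    "kmeans_fit",
    "control_score",
    "select_k",
    "map_roles",
    "composition_over_time",
]


@dataclass
class SubpopulationModel:
    """A fitted k-means partition plus its cluster-to-role map."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    score_trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    role_map: Dict[int, str] = field(default_factory=dict)
    missing_roles: List[str] = field(default_factory=list)

    def roles(self) -> np.ndarray:
        """Per-cell role labels through the role map."""
        if not self.role_map:
            raise ValueError("role_map not assigned; call map_roles first")
        lut = np.empty(self.k, dtype=object)
        for c, r in self.role_map.items():
            lut[c] = r
        return lut[self.labels]


def kmeans_fit(X: np.ndarray, k: int, seed: int = 0,
               n_init: int = 10) -> Tuple[np.ndarray, np.ndarray]:
    """Best-of-``n_init`` k-means++ fit; returns (labels, centroids)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k ({k}) exceeds number of rows ({X.shape[0]})")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def control_score(labels: np.ndarray, control_mask: np.ndarray,
                  score: str = "recall_purity") -> Tuple[float, int]:
    """Control-anchoring score of a partition: max over clusters of
    recall x purity (or recall alone) of the control cells.

    Returns (score, best cluster id).  Invariant to cluster relabeling.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if not control_mask.any():
        raise ValueError("control set is empty")
    n_control = control_mask.sum()
    best, best_c = -1.0, -1
    for c in np.unique(labels):
        in_c = labels == c
        ctrl_in_c = (in_c & control_mask).sum()
        recall = ctrl_in_c / n_control
        purity = ctrl_in_c / in_c.sum()
        s = recall if score == "recall" else recall * purity
        if s > best:
            best, best_c = s, int(c)
    return float(best), best_c


def select_k(
    X: np.ndarray,
    control_mask: np.ndarray,
    k_range: Sequence[int] = tuple(range(2, 21)),
    seed: int = 0,
    n_init: int = 10,
    score: str = "recall_purity",
) -> Tuple[int, SubpopulationModel]:
    """Choose the cluster count maximizing the control-anchoring score.

    Fits k-means for every k in ``k_range``, scores each partition, and
    returns the argmax (ties toward smaller k) with its fitted model and the
    full score trace.
    """
    if not np.asarray(control_mask, dtype=bool).any():
        raise ValueError("control set is empty")
    rows = []
    fits = {}
    for k in k_range:
        labels, centroids = kmeans_fit(X, k, seed=seed, n_init=n_init)
        s, _ = control_score(labels, control_mask, score=score)
        rows.append({"k": k, "score": s})
        fits[k] = (labels, centroids)
    trace = pd.DataFrame(rows)
    best_k = int(trace.loc[trace["score"].idxmax(), "k"])  # idxmax -> first max
    labels, centroids = fits[best_k]
    model = SubpopulationModel(k=best_k, centroids=centroids, labels=labels,
                               score_trace=trace)
    return best_k, model


def _late_occupancy(labels: np.ndarray, days: np.ndarray, c: int,
                    time_points: np.ndarray, n_final: int) -> float:
    """Share of cluster ``c``'s cells that fall in the final ``n_final`` time
    points.  Terminal populations, whose emergence weights keep rising,
    concentrate well above the uniform share; transitional populations peak
    mid-course and do not."""
    in_c = labels == c
    total = in_c.sum()
    if total == 0:
        return 0.0
    late_days = set(time_points[-n_final:])
    late = sum((in_c & (days == d)).sum() for d in late_days)
    return late / total


def map_roles(
    model: SubpopulationModel,
    columns: Sequence[str],
    days: np.ndarray,
    control_day: int = 0,
    marker_panel: Sequence[str] = SENESCENCE_MARKERS,
    area_column: str = "nuclear_area_px",
) -> Dict[int, str]:
    """Assign each cluster one of the six biological roles.

    Deterministic rules on the fitted centroids (in z-normalized feature
    space):

    1. healthy — the cluster scoring highest on recall x purity of the
       day-``control_day`` cells;
    2. terminal candidates — non-healthy clusters whose occupancy
       concentrates in the final third of the time course (share > 1.2x the
       uniform share) and whose centroid distance from healthy is at least
       the median such distance (relaxed to the three most distant
       late-concentrated clusters when the gate under-selects);
    3. among terminals, large-nuclear has the top centroid nuclear area and
       high-concentration the top mean senescence-marker concentration
       (``<marker>_nuc_mean`` columns); remaining terminals are
       non-senescent terminal;
    4. clusters on the centroid minimum-spanning-tree path from healthy to a
       senescent terminal are senescent-transitional;
    5. every other cluster merges into non-senescent transitional.

    With fewer than three terminal candidates, roles are assigned as far as
    possible and the rest reported in ``model.missing_roles``.
    """
    columns = list(columns)
    labels, centroids = model.labels, model.centroids
    control_mask = days == control_day
    _, healthy_c = control_score(labels, control_mask)

    time_points = np.unique(days)
    n_final = max(1, int(np.ceil(len(time_points) / 3)))
    uniform_share = n_final / len(time_points)

    dists = np.linalg.norm(centroids - centroids[healthy_c], axis=1)
    others = [c for c in range(model.k) if c != healthy_c]
    late = [c for c in others
            if _late_occupancy(labels, days, c, time_points, n_final)
            > 1.2 * uniform_share]
    med = np.median(dists[others]) if others else 0.0
    candidates = [c for c in late if dists[c] >= med]
    if len(candidates) < 3 and len(late) >= 3:
        # distance gate too strict for this partition: keep the three most
        # distant late-concentrated clusters
        candidates = sorted(late, key=lambda c: -dists[c])[:3]

    area_i = columns.index(area_column)
    conc_i = [columns.index(f"{m}_nuc_mean") for m in marker_panel
              if f"{m}_nuc_mean" in columns]
    area_z = centroids[:, area_i]
    conc_z = centroids[:, conc_i].mean(axis=1) if conc_i else np.zeros(model.k)

    role_map: Dict[int, str] = {healthy_c: HEALTHY}
    missing: List[str] = []
    terminals: Dict[int, str] = {}
    if len(candidates) == 0:
        missing += [LARGE_NUCLEAR, HIGH_CONCENTRATION, NONSENESCENT_TERMINAL]
    elif len(candidates) <= 3:
        pool = list(candidates)
        ln = max(pool, key=lambda c: area_z[c])
        terminals[ln] = LARGE_NUCLEAR
        pool.remove(ln)
        if pool:
            hc = max(pool, key=lambda c: conc_z[c])
            terminals[hc] = HIGH_CONCENTRATION
            pool.remove(hc)
        else:
            missing.append(HIGH_CONCENTRATION)
        if pool:
            terminals[pool[0]] = NONSENESCENT_TERMINAL
        else:
            missing.append(NONSENESCENT_TERMINAL)
    else:
        # more candidates than roles (k above 6): classify each by its
        # dominant signature, thresholding at one z-unit
        ln = max(candidates, key=lambda c: area_z[c])
        hc = max(candidates, key=lambda c: conc_z[c])
        for c in candidates:
            if c == ln or (area_z[c] >= 1.0 and area_z[c] >= conc_z[c]):
                terminals[c] = LARGE_NUCLEAR
            elif c == hc or conc_z[c] >= 1.0:
                terminals[c] = HIGH_CONCENTRATION
            else:
                terminals[c] = NONSENESCENT_TERMINAL
    role_map.update(terminals)

    # senescent transitional: clusters between healthy and senescent
    # terminals on the centroid MST
    import networkx as nx

    from .lineage import build_mst

    if model.k >= 2:
        tree = build_mst(centroids)
        senescent_terms = [c for c, r in terminals.items()
                           if r in (LARGE_NUCLEAR, HIGH_CONCENTRATION)]
        on_path: set = set()
        for term in senescent_terms:
            path = nx.shortest_path(tree, healthy_c, term)
            on_path.update(path[1:-1])
        for c in on_path:
            if c not in role_map:
                role_map[c] = SENESCENT_TRANSITIONAL
        if not on_path and model.k > len(role_map):
            missing.append(SENESCENT_TRANSITIONAL)

    for c in range(model.k):
        role_map.setdefault(c, NONSENESCENT_TRANSITIONAL)
    if NONSENESCENT_TRANSITIONAL not in role_map.values():
        missing.append(NONSENESCENT_TRANSITIONAL)

    model.role_map = role_map
    model.missing_roles = sorted(set(missing))
    return role_map


def composition_over_time(labels: np.ndarray, role_map: Dict[int, str],
                          days: np.ndarray) -> pd.DataFrame:
    """Per-day role fractions (rows sum to 1).

    Returns a DataFrame indexed by day with one column per role present.
    """
    if len(labels) == 0:
        raise ValueError("no cells")
    roles = np.array([role_map[int(c)] for c in labels], dtype=object)
    df = pd.DataFrame({"day": days, "role": roles})
    comp = (df.groupby(["day", "role"]).size().unstack(fill_value=0))
    comp = comp.div(comp.sum(axis=1), axis=0)
    for role in ROLES:
        if role not in comp.columns:
            comp[role] = 0.0
    return comp[[r for r in ROLES]]
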