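"""Feature normalization, density-preserving subsampling, and a 3D
diffusion-potential embedding.

The embedding follows the heat-diffusion potential construction: an adaptive
alpha-decay kernel on k-nearest-neighbor distances, symmetrization, row
normalization into a diffusion operator P, diffusion for t steps (t chosen by
the von Neumann entropy knee when automatic), the log-potential
``-log(P^t + eps)``, and metric MDS of the potential distances down to three
dimensions (classical-scaling initialization refined by SMACOF).  P^t is
computed exactly through the eigendecomposition of the symmetric conjugate
operator, so the pipeline is deterministic given its inputs.

Subsampling reimplements density-preserving geometric sketching: cells are
hashed into the boxes of a random-projection lattice and boxes are sampled
uniformly, which over-represents rare subpopulations relative to uniform
row sampling — the property that matters for keeping minority senescence
states visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FeatureMatrix",
    "EmbeddingResult",
    "znormalize",
    "subsample_per_timepoint",
    "diffusion_operator",
    "phate_embed",
]


@dataclass
class FeatureMatrix:
    """A z-normalized cell x feature matrix with its normalization statistics."""

    X: np.ndarray
    columns: List[str]
    cell_ids: np.ndarray
    days: np.ndarray
    mean_: np.ndarray
    std_: np.ndarray
    dropped_columns: List[str] = field(default_factory=list)

    def inverse_transform(self, X: Optional[np.ndarray] = None) -> np.ndarray:
        """Undo the z-normalization (columns dropped as constant are gone)."""
        if X is None:
            X = self.X
        return X * self.std_ + self.mean_


def znormalize(
    features: pd.DataFrame,
    feature_columns: Optional[Sequence[str]] = None,
    missing: str = "drop",
) -> FeatureMatrix:
    """Column-wise z-normalization (population SD) of the feature table.

    ``features`` must carry ``cell_id`` and ``day`` columns; all remaining
    numeric columns are used unless ``feature_columns`` narrows them.
    Constant columns are dropped with a warning rather than raising.
    Rows with missing values are dropped (``missing='drop'``) or imputed by
    the column median (``missing='median'``) before normalization.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 rows to normalize")
    if feature_columns is None:
        feature_columns = [c for c in features.columns
                           if c not in ("cell_id", "day", "touches_border")
                           and np.issubdtype(features[c].dtype, np.number)]
    sub = features[list(feature_columns)].astype(float)
    meta = features[["cell_id", "day"]]

    if sub.isna().any().any():
        if missing == "drop":
            keep = ~sub.isna().any(axis=1)
            sub, meta = sub.loc[keep], meta.loc[keep]
        elif missing == "median":
            sub = sub.fillna(sub.median())
        else:
            raise ValueError("missing must be 'drop' or 'median'")

    X = sub.to_numpy()
    mean = X.mean(axis=0)
    std = X.std(axis=0)          # population SD convention
    const = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    dropped = [c for c, bad in zip(sub.columns, const) if bad]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
    keep_cols = ~const
    X = (X[:, keep_cols] - mean[keep_cols]) / std[keep_cols]
    return FeatureMatrix(
        X=X,
        columns=[c for c in sub.columns if c not in dropped],
        cell_ids=meta["cell_id"].to_numpy(),
        days=meta["day"].to_numpy(),
        mean_=mean[keep_cols],
        std_=std[keep_cols],
        dropped_columns=dropped,
    )


def subsample_per_timepoint(
    fm: FeatureMatrix,
    n: int = 1200,
    seed: int = 0,
    n_projections: int = 5,
) -> np.ndarray:
    """Density-preserving sketch: row indices keeping <= ``n`` cells per day.

    Cells of each time point are hashed into the boxes of a random-projection
    lattice whose resolution is doubled until at least ``n`` boxes are
    occupied (or a cap is reached); boxes are then visited round-robin in
    random order, taking one cell per visit.  Time points with <= ``n`` cells
    pass through entirely.  Deterministic under a fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    picked: List[np.ndarray] = []
    for day in np.unique(fm.days):
        idx = np.flatnonzero(fm.days == day)
        if idx.size <= n:
            picked.append(idx)
            continue
        proj = fm.X[idx] @ rng.normal(size=(fm.X.shape[1], n_projections))
        lo, hi = proj.min(axis=0), proj.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        unit = (proj - lo) / span
        bins = 2
        boxes = None
        while bins <= 1024:
            codes = np.minimum((unit * bins).astype(np.int64), bins - 1)
            _, boxes = np.unique(codes, axis=0, return_inverse=True)
            if boxes.max() + 1 >= n:
                break
            bins *= 2
        order: Dict[int, List[int]] = {}
        for local_i, b in enumerate(boxes):
            order.setdefault(int(b), []).append(local_i)
        box_ids = list(order)
        rng.shuffle(box_ids)
        for b in box_ids:
            members = order[b]
            rng.shuffle(members)
        take: List[int] = []
        round_i = 0
        while len(take) < n:
            added = False
            for b in box_ids:
                members = order[b]
                if round_i < len(members):
                    take.append(members[round_i])
                    added = True
                    if len(take) == n:
                        break
            if not added:
                break
            round_i += 1
        picked.append(idx[np.sort(np.asarray(take[:n]))])
    return np.concatenate(picked)


@dataclass
class EmbeddingResult:
    """3D diffusion-potential coordinates, row-aligned with their input."""

    coordinates: np.ndarray
    knn: int
    decay: float
    t: int
    seed: int
    stress_trace: np.ndarray
    vne_trace: Optional[np.ndarray] = None


def diffusion_operator(
    X: np.ndarray, knn: int = 15, decay: float = 40.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Adaptive alpha-decay kernel and its row-stochastic diffusion operator.

    Returns ``(P, K)``: K is the symmetrized kernel, P = K / rowsum(K).
    The adaptive bandwidth of each cell is its distance to the ``knn``-th
    nearest neighbor.  A disconnected kernel graph is bridged by the minimal
    inter-component links (logged via warning).
    """
    n = X.shape[0]
    if knn >= n:
        raise ValueError(f"knn ({knn}) must be < number of rows ({n})")
    D = squareform(pdist(X))
    sigma = np.sort(D, axis=1)[:, knn]
    sigma = np.maximum(sigma, 1e-12)
    with np.errstate(over="ignore"):
        K = 0.5 * (np.exp(-((D / sigma[:, None]) ** decay))
                   + np.exp(-((D / sigma[None, :]) ** decay)))
    np.fill_diagonal(K, 1.0)

    # connectivity: bridge components through their closest pair
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix

    adj = csr_matrix((K > 1e-12).astype(np.int8))
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(f"kNN kernel graph has {n_comp} components; bridging",
                      stacklevel=2)
        for c in range(1, n_comp):
            a = np.flatnonzero(comp == 0)
            b = np.flatnonzero(comp == c)
            sub = D[np.ix_(a, b)]
            i, j = np.unravel_index(np.argmin(sub), sub.shape)
            K[a[i], b[j]] = K[b[j], a[i]] = np.exp(-1.0)
            comp[comp == c] = 0

    P = K / K.sum(axis=1, keepdims=True)
    return P, K


def _vne_knee(lams: np.ndarray, t_max: int = 100) -> Tuple[int, np.ndarray]:
    """Von Neumann entropy of the diffused spectrum; knee by max distance
    from the chord."""
    lams = np.abs(lams)
    ts = np.arange(1, t_max + 1)
    H = np.empty(t_max)
    for i, t in enumerate(ts):
        p = lams ** t
        s = p.sum()
        if s <= 0:
            H[i] = 0.0
            continue
        p = p / s
        p = p[p > 0]
        H[i] = -(p * np.log(p)).sum()
    x = (ts - ts[0]) / (ts[-1] - ts[0])
    y = (H - H[-1]) / max(H[0] - H[-1], 1e-12)
    d = np.abs(y - (1 - x))
    knee = int(ts[np.argmax(d)])
    return knee, H


def _classical_mds(D2: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson scaling of a squared-distance matrix."""
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def _smacof(D: np.ndarray, init: np.ndarray, max_iter: int = 300,
            tol: float = 1e-6) -> Tuple[np.ndarray, np.ndarray]:
    """SMACOF metric-MDS refinement; returns coordinates and the stress trace
    (monotonically non-increasing by the majorization guarantee)."""
    X = init.copy()
    n = D.shape[0]
    trace = []
    old = np.inf
    for _ in range(max_iter):
        dX = squareform(pdist(X))
        stress = ((D - dX) ** 2).sum() / 2.0
        trace.append(stress)
        if old - stress < tol * max(old, 1.0):
            break
        old = stress
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dX > 0, D / dX, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
    return X, np.asarray(trace)


def phate_embed(
    X: np.ndarray,
    dims: int = 3,
    knn: int = 15,
    decay: float = 40.0,
    t: Optional[int] = None,
    seed: int = 0,
    eps: float = 1e-7,
    potential: str = "sqrt",
    mds_max_iter: int = 300,
    mds_tol: float = 1e-6,
) -> EmbeddingResult:
    """Diffusion-potential embedding of a (normalized) feature matrix.

    ``t=None`` selects the diffusion time by the von Neumann entropy knee.
    P^t is evaluated exactly via the eigendecomposition of the symmetric
    conjugate A = Dg^-1/2 K Dg^-1/2 (P^t = Dg^-1/2 A^t Dg^1/2), followed by
    the potential transform and metric MDS.

    ``potential='sqrt'`` (default) embeds distances between the rows of
    2*sqrt(P^t) (a Hellinger-type diffusion distance); ``'log'`` uses the
    classical log potential -log(P^t + eps).  The sqrt potential weights
    strong transitions, so small peripheral subpopulations are placed by
    whom they actually exchange diffusion mass with; the log potential
    weights the deep tail, where every weakly connected subpopulation looks
    alike and rare terminal states collapse onto each other.
    """
    n = X.shape[0]
    if n < dims + 2:
        raise ValueError(f"need at least {dims + 2} rows, got {n}")
    P, K = diffusion_operator(X, knn=knn, decay=decay)
    d = K.sum(axis=1)
    d_is = 1.0 / np.sqrt(d)
    A = K * d_is[:, None] * d_is[None, :]
    lams, Q = np.linalg.eigh(A)

    vne = None
    if t is None:
        t, vne = _vne_knee(lams)

    At = (Q * (np.sign(lams) * np.abs(lams) ** t)) @ Q.T
    Pt = (At * d_is[:, None]) * np.sqrt(d)[None, :]
    Pt = np.clip(Pt, 0.0, None)
    if potential == "log":
        U = -np.log(Pt + eps)
    elif potential == "sqrt":
        U = 2.0 * np.sqrt(Pt)
    else:
        raise ValueError("potential must be 'sqrt' or 'log'")
    pot_D = squareform(pdist(U))

    init = _classical_mds(pot_D ** 2, dims)
    coords, trace = _smacof(pot_D, init, max_iter=mds_max_iter, tol=mds_tol)
    return EmbeddingResult(coordinates=coords, knn=knn, decay=decay, t=int(t),
                           seed=seed, stress_trace=trace, vne_trace=vne)
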