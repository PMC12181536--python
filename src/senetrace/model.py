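"""Model/results interface over the full analysis.

``SenescenceTrajectoryModel`` wraps a per-cell feature table (from the
quantification stage or the synthetic generator) and ``fit()`` runs the
analysis chain — z-normalization, per-time-point sketch subsampling,
diffusion-potential embedding, control-anchored k-means with role mapping,
lineage/pseudotime inference — returning a ``TrajectoryResults`` object that
carries the estimates and exposes the pseudotime statistics, composition
tables and plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import embed as _embed
from . import lineage as _lineage
from . import pstats as _pstats
from .synthetic import (
    HEALTHY,
    HIGH_CONCENTRATION,
    LARGE_NUCLEAR,
    ROLES,
    SENESCENCE_MARKERS,
)

__all__ = ["SenescenceTrajectoryModel", "TrajectoryResults"]


class SenescenceTrajectoryModel:
    """Single-cell senescence-trajectory analysis of a feature table.

    Parameters
    ----------
    features
        Per-cell table with ``cell_id``, ``day`` and feature columns
        (``nuclear_area_px`` plus per-marker nuclear mean/total and
        cytoplasmic mean).
    control_day
        The untreated anchor time point (default 0); its cells define the
        healthy population for cluster-count selection and lineage rooting.
    feature_columns
        Optional subset of feature columns to analyze.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        control_day: int = 0,
        feature_columns: Optional[Sequence[str]] = None,
        marker_panel: Sequence[str] = SENESCENCE_MARKERS,
    ) -> None:
        for required in ("cell_id", "day"):
            if required not in features.columns:
                raise ValueError(f"features table must have a '{required}' column")
        if control_day not in set(features["day"]):
            raise ValueError(f"control day {control_day} absent from table")
        self.features = features.reset_index(drop=True)
        self.control_day = control_day
        self.feature_columns = list(feature_columns) if feature_columns else None
        self.marker_panel = list(marker_panel)

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, **kwargs) -> "SenescenceTrajectoryModel":
        return cls(features, **kwargs)

    @classmethod
    def from_csv(cls, path: str, **kwargs) -> "SenescenceTrajectoryModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(
        self,
        seed: int = 0,
        subsample_n: int = 1200,
        k_range: Sequence[int] = tuple(range(2, 21)),
        n_init: int = 10,
        knn: int = 15,
        decay: float = 40.0,
        t: Optional[int] = 40,
        compute_embedding: bool = True,
        lineage_on_roles: bool = True,
        truncation_slack: float = 2.0,
    ) -> "TrajectoryResults":
        """Run the analysis chain and return the results object.

        Clustering runs on the full z-normalized feature matrix; the
        embedding (and hence lineage inference) runs on the per-time-point
        subsample.  ``compute_embedding=False`` stops after clustering and
        composition, which is enough for composition-over-time questions.
        ``lineage_on_roles`` merges clusters into their six roles before the
        lineage tree is built, reproducing the three-terminal topology;
        set it False to build the tree over raw clusters.
        """
        fm = _embed.znormalize(self.features, self.feature_columns)
        control_mask = fm.days == self.control_day

        k_star, model = _cluster.select_k(
            fm.X, control_mask, k_range=k_range, seed=seed, n_init=n_init)
        role_map = _cluster.map_roles(
            model, fm.columns, fm.days, control_day=self.control_day,
            marker_panel=self.marker_panel)
        composition = _cluster.composition_over_time(model.labels, role_map, fm.days)

        sub_idx = _embed.subsample_per_timepoint(fm, n=subsample_n, seed=seed)
        embedding = None
        lineage_set = None
        lineage_roles: List[str] = []
        if compute_embedding:
            embedding = _embed.phate_embed(
                fm.X[sub_idx], dims=3, knn=knn, decay=decay, t=t, seed=seed)
            sub_labels = model.labels[sub_idx]
            sub_days = fm.days[sub_idx]
            if lineage_on_roles:
                roles_per_cell = np.array([role_map[int(c)] for c in sub_labels])
                present = [r for r in ROLES if (roles_per_cell == r).any()]
                group_of = {r: i for i, r in enumerate(present)}
                groups = np.array([group_of[r] for r in roles_per_cell])
                root = group_of[HEALTHY]
                lineage_set = _lineage.infer_lineages(
                    embedding.coordinates, groups, root, cell_days=sub_days,
                    slack=truncation_slack)
                lineage_roles = present
            else:
                _, healthy_c = _cluster.control_score(
                    sub_labels, sub_days == self.control_day)
                lineage_set = _lineage.infer_lineages(
                    embedding.coordinates, sub_labels, healthy_c,
                    cell_days=sub_days, slack=truncation_slack)
                lineage_roles = []

        return TrajectoryResults(
            model=self,
            feature_matrix=fm,
            k=k_star,
            subpop_model=model,
            role_map=role_map,
            composition=composition,
            subsample_indices=sub_idx,
            embedding=embedding,
            lineage_set=lineage_set,
            lineage_node_roles=lineage_roles,
            seed=seed,
        )


@dataclass
class TrajectoryResults:
    """Fitted senescence-trajectory analysis.

    Lineages are indexed 0..L-1; ``lineage_names`` gives each one the role
    name of its terminal cluster.
    """

    model: SenescenceTrajectoryModel
    feature_matrix: _embed.FeatureMatrix
    k: int
    subpop_model: _cluster.SubpopulationModel
    role_map: Dict[int, str]
    composition: pd.DataFrame
    subsample_indices: np.ndarray
    embedding: Optional[_embed.EmbeddingResult]
    lineage_set: Optional[_lineage.LineageSet]
    lineage_node_roles: List[str] = field(default_factory=list)
    seed: int = 0

    # ---- lineage conveniences -------------------------------------------
    @property
    def lineage_names(self) -> List[str]:
        """Terminal role (or cluster id) of each lineage."""
        if self.lineage_set is None:
            return []
        names = []
        for path in self.lineage_set.lineages:
            leaf = path[-1]
            if self.lineage_node_roles:
                names.append(self.lineage_node_roles[leaf])
            else:
                names.append(str(leaf))
        return names

    def lineage_index(self, terminal_role: str) -> int:
        names = self.lineage_names
        if terminal_role not in names:
            raise KeyError(f"no lineage ends in {terminal_role!r}; have {names}")
        return names.index(terminal_role)

    def lineage_cells(self, lineage: int, truncated: bool = True) -> pd.DataFrame:
        """Feature rows of a lineage's member cells joined with pseudotime
        and weight (rows beyond the truncation point dropped by default)."""
        if self.lineage_set is None:
            raise ValueError("fit was run without the embedding/lineage stage")
        mem = self.lineage_set.members(lineage, truncated=truncated)
        global_idx = self.subsample_indices[mem["index"].to_numpy()]
        rows = self.model.features.iloc[global_idx].reset_index(drop=True)
        rows["pseudotime"] = mem["pseudotime"].to_numpy()
        rows["weight"] = mem["weight"].to_numpy()
        return rows

    # ---- pseudotime statistics ------------------------------------------
    def trend_curve(self, feature: str, lineage: int,
                    span: float = 0.3, grid_n: int = 100) -> _pstats.TrendCurve:
        cells = self.lineage_cells(lineage)
        return _pstats.loess_curve(
            cells["pseudotime"].to_numpy(), cells[feature].to_numpy(),
            span=span, grid_n=grid_n, lineage=lineage, feature=feature,
            grid_max=self.lineage_set.length(lineage))

    def compare(self, feature: str, lineage_a: int, lineage_b: int,
                window: str = "full") -> _pstats.LineageComparison:
        """KS comparison of a feature between two lineages' member cells,
        over the whole lineage or the final 10% window."""
        va = self._window_values(feature, lineage_a, window)
        vb = self._window_values(feature, lineage_b, window)
        return _pstats.compare_lineages_ks(
            va, vb, feature=feature, lineage_a=lineage_a, lineage_b=lineage_b,
            window=window)

    def final_window(self, lineage: int, fraction: float = 0.10,
                     features: Optional[Sequence[str]] = None) -> pd.DataFrame:
        cells = self.lineage_cells(lineage)
        cols = list(features) if features else self.feature_matrix.columns
        return _pstats.final_window_summary(
            cells["pseudotime"].to_numpy(), cells[cols], fraction=fraction,
            lineage_length=self.lineage_set.length(lineage))

    def _window_values(self, feature: str, lineage: int, window: str) -> np.ndarray:
        cells = self.lineage_cells(lineage)
        if window == "full":
            return cells[feature].to_numpy()
        if window == "final_10pct":
            L = self.lineage_set.length(lineage)
            return cells.loc[cells["pseudotime"] >= 0.9 * L, feature].to_numpy()
        raise ValueError("window must be 'full' or 'final_10pct'")

    # ---- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the fit."""
        lines = ["Senescence trajectory analysis", "=" * 34]
        n = len(self.model.features)
        days = np.unique(self.feature_matrix.days)
        lines.append(f"cells: {n}   time points: {len(days)} "
                     f"(day {days.min()}..{days.max()})   seed: {self.seed}")
        trace = self.subpop_model.score_trace
        best = trace.loc[trace["score"].idxmax()]
        lines.append(f"clusters: k={self.k} selected by control anchoring "
                     f"(score {best['score']:.3f})")
        counts = pd.Series(self.subpop_model.roles()).value_counts()
        lines.append("roles (cells): " + ", ".join(
            f"{r}={counts.get(r, 0)}" for r in ROLES))
        if self.subpop_model.missing_roles:
            lines.append(f"missing roles: {self.subpop_model.missing_roles}")
        for day, frac in self.day_role_fractions().items():
            lines.append(day + ": " + frac)
        if self.lineage_set is not None:
            lines.append(f"lineages: {len(self.lineage_set.lineages)} "
                         f"(terminal roles: {', '.join(self.lineage_names)})")
            for li, name in enumerate(self.lineage_names):
                tau = self.lineage_set.truncations.get(li)
                trunc = f", truncated at {tau:.3g}" if tau is not None else ""
                lines.append(f"  lineage {li} -> {name}: length "
                             f"{self.lineage_set.length(li):.3g}{trunc}")
        return "\n".join(lines)

    def day_role_fractions(self) -> Dict[str, str]:
        out = {}
        for day in (2, 31):
            if day in self.composition.index:
                row = self.composition.loc[day]
                out[f"day {day}"] = ", ".join(
                    f"{r}={row[r]:.3f}" for r in ROLES if row[r] > 0)
        return out

    # ---- plotting --------------------------------------------------------
    def plot_embedding(self, color_by: str = "role", ax=None):
        """3D scatter of the embedding colored by role or day."""
        if self.embedding is None:
            raise ValueError("no embedding was computed")
        import matplotlib.pyplot as plt

        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        coords = self.embedding.coordinates
        sub_labels = self.subpop_model.labels[self.subsample_indices]
        if color_by == "role":
            roles = np.array([self.role_map[int(c)] for c in sub_labels])
            for r in ROLES:
                m = roles == r
                if m.any():
                    ax.scatter(*coords[m].T, s=4, label=r)
            ax.legend(fontsize=6)
        else:
            sc = ax.scatter(*coords.T, s=4,
                            c=self.feature_matrix.days[self.subsample_indices])
            plt.colorbar(sc, ax=ax, label="day")
        return ax

    def plot_trend(self, feature: str, ax=None, span: float = 0.3):
        """Loess trend of one feature along every lineage, final 10% shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for li, name in enumerate(self.lineage_names):
            tc = self.trend_curve(feature, li, span=span)
            ax.plot(tc.grid, tc.mean, label=name)
            ax.fill_between(tc.grid, tc.mean - tc.band, tc.mean + tc.band,
                            alpha=0.2)
            L = self.lineage_set.length(li)
            ax.axvspan(0.9 * L, L, color="gray", alpha=0.1)
        ax.set_xlabel("pseudotime")
        ax.set_ylabel(feature)
        ax.legend(fontsize=7)
        return ax
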