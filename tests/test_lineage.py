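"""Lineage-stage oracles: brute-force MST checks, principal-curve fixed
points, pseudotime geometry invariances, and the backward-time truncation
rule on constructed lineages."""

import itertools

import networkx as nx
import numpy as np
import pytest

from senetrace import lineage as lin


def brute_force_mst_weight(centroids):
    """Minimum spanning-tree weight by enumeration over all spanning trees
    (Cayley: feasible for <= 7 nodes)."""
    n = len(centroids)
    nodes = range(n)
    all_edges = [(i, j) for i in nodes for j in nodes if i < j]
    best = np.inf
    for choice in itertools.combinations(all_edges, n - 1):
        g = nx.Graph(choice)
        if g.number_of_nodes() == n and nx.is_connected(g):
            w = sum(np.linalg.norm(centroids[i] - centroids[j])
                    for i, j in choice)
            best = min(best, w)
    return best


class TestBuildMST:
    def test_two_clusters_single_edge(self):
        tree = lin.build_mst(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert tree.number_of_edges() == 1

    def test_collinear_clusters_form_path(self):
        C = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [3.0, 0]])
        tree = lin.build_mst(C)
        degs = sorted(d for _, d in tree.degree)
        assert degs == [1, 1, 2, 2]
        assert tree.has_edge(0, 1) and tree.has_edge(1, 2) and tree.has_edge(2, 3)

    def test_star_geometry_recovered(self):
        C = np.array([[0.0, 0], [3.0, 0], [-1.5, 2.6], [-1.5, -2.6]])
        tree = lin.build_mst(C)
        assert tree.degree(0) == 3

    def test_total_weight_matches_brute_force(self, rng):
        for _ in range(5):
            C = rng.normal(size=(6, 3))
            tree = lin.build_mst(C)
            w = sum(d["weight"] for _, _, d in tree.edges(data=True))
            assert w == pytest.approx(brute_force_mst_weight(C), rel=1e-9)

    def test_duplicate_centroids_warned_but_valid(self):
        with pytest.warns(UserWarning, match="duplicate"):
            tree = lin.build_mst(np.array([[0.0, 0], [0.0, 0], [1.0, 0]]))
        assert nx.is_tree(tree)


class TestExtractLineages:
    def test_star_root(self):
        tree = nx.Graph([(0, 1), (0, 2), (0, 3)])
        paths = lin.extract_lineages(tree, 0)
        assert sorted(p[-1] for p in paths) == [1, 2, 3]
        assert all(p[0] == 0 and len(p) == 2 for p in paths)

    def test_path_graph_single_lineage(self):
        tree = nx.Graph([(0, 1), (1, 2), (2, 3)])
        paths = lin.extract_lineages(tree, 0)
        assert paths == [[0, 1, 2, 3]]

    def test_missing_root_rejected(self):
        with pytest.raises(ValueError):
            lin.extract_lineages(nx.Graph([(0, 1)]), 5)


class TestPrincipalCurves:
    def test_straight_line_is_fixed_point(self, rng):
        t = np.sort(rng.uniform(0, 10, 200))
        coords = np.c_[t, np.zeros_like(t), np.zeros_like(t)]
        labels = (t > 5).astype(int)
        curves, table, conv, _ = lin.fit_principal_curves(
            coords, labels, [[0, 1]])
        assert conv[0]
        # curve stays on the line
        assert np.abs(curves[0][:, 1:]).max() < 1e-6
        # pseudotime is a monotone (affine) function of position
        order = np.argsort(table["index"].to_numpy())
        pt = table["pseudotime"].to_numpy()[order]
        np.testing.assert_allclose(pt, pt[0] + (t - t[0]), atol=1e-6)

    def test_noisy_arc_rank_correlation(self, rng):
        from scipy.stats import spearmanr

        theta = np.sort(rng.uniform(0, np.pi, 500))
        coords = np.c_[np.cos(theta), np.sin(theta),
                       np.zeros_like(theta)] + rng.normal(0, 0.05, (500, 3))
        labels = np.digitize(theta, [np.pi / 3, 2 * np.pi / 3])
        curves, table, _, _ = lin.fit_principal_curves(
            coords, labels, [[0, 1, 2]])
        rho = spearmanr(table["pseudotime"], theta[table["index"]]).statistic
        assert abs(rho) >= 0.95

    def test_equidistant_cell_has_half_weights(self):
        # two parallel straight lineages; a cell midway between them
        line = np.c_[np.linspace(0, 10, 50), np.zeros(50), np.zeros(50)]
        up = line + [0, 2.0, 0]
        mid = np.array([[5.0, 1.0, 0.0]])
        coords = np.vstack([line, up, mid])
        labels = np.r_[np.zeros(50, int), np.ones(50, int), [2]]
        # cluster 2 is shared by both lineages
        _, table, _, _ = lin.fit_principal_curves(
            coords, labels, [[0, 2], [1, 2]], max_iter=0)
        w = table[table["index"] == 100].sort_values("lineage")["weight"]
        np.testing.assert_allclose(w, [0.5, 0.5], atol=0.05)

    def test_pseudotime_rigid_motion_invariance(self, rng):
        t = np.sort(rng.uniform(0, 5, 150))
        coords = np.c_[t, 0.3 * t, np.zeros_like(t)]
        labels = (t > 2.5).astype(int)
        _, tab_a, _, _ = lin.fit_principal_curves(coords, labels, [[0, 1]])
        # rotate + translate
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        _, tab_b, _, _ = lin.fit_principal_curves(
            coords @ R.T + [1.0, -2.0, 3.0], labels, [[0, 1]])
        np.testing.assert_allclose(tab_a["pseudotime"], tab_b["pseudotime"],
                                   atol=1e-6)


class TestTruncateBackward:
    def test_monotone_day_no_truncation(self, rng):
        pt = np.sort(rng.uniform(0, 10, 400))
        day = np.floor(pt * 3)
        assert lin.truncate_backward(pt, day) is None

    def test_constant_day_no_truncation(self, rng):
        pt = np.sort(rng.uniform(0, 10, 400))
        assert lin.truncate_backward(pt, np.full(400, 7.0)) is None

    def test_constructed_reversal_located(self, rng):
        # day rises to pseudotime 6, then the appended tail reverses
        pt = np.sort(rng.uniform(0, 10, 1000))
        day = np.where(pt <= 6.0, pt * 5, 30 - (pt - 6.0) * 6)
        tau = lin.truncate_backward(pt, day)
        assert tau is not None
        assert abs(tau - 6.0) < 0.05 * 10.0

    def test_noisy_monotone_not_truncated_with_slack(self, rng):
        pt = np.sort(rng.uniform(0, 10, 800))
        day = pt * 3 + rng.normal(0, 2.0, 800)
        assert lin.truncate_backward(pt, day, slack=2.0) is None

    def test_too_few_cells_warns(self):
        with pytest.warns(UserWarning, match="window"):
            assert lin.truncate_backward(np.arange(5.0), np.arange(5.0)) is None


class TestPlantedLineageStructure:
    def test_three_lineages_through_transitional(self, fitted):
        res, _ = fitted
        assert len(res.lineage_set.lineages) == 3
        names = sorted(res.lineage_names)
        assert names == ["high_concentration", "large_nuclear",
                         "nonsenescent_terminal"]
        roles = res.lineage_node_roles
        for path in res.lineage_set.lineages:
            assert roles[path[0]] == "healthy"
            if roles[path[-1]] in ("large_nuclear", "high_concentration"):
                assert "senescent_transitional" in [roles[c] for c in path]

    def test_cluster_order_respected_along_pseudotime(self, fitted):
        res, truth = fitted
        li = res.lineage_index("large_nuclear")
        cells = res.lineage_cells(li)
        sub_truth = truth.set_index("cell_id").loc[cells["cell_id"]]
        means = cells.groupby(sub_truth["role"].to_numpy())["pseudotime"].mean()
        assert means["healthy"] < means["senescent_transitional"] \
            < means["large_nuclear"]

    def test_high_concentration_lineage_has_top_terminal_il6(self, fitted):
        res, _ = fitted
        il6 = {}
        for name in res.lineage_names:
            li = res.lineage_index(name)
            cells = res.lineage_cells(li)
            top = cells[cells["pseudotime"] >=
                        0.9 * cells["pseudotime"].max()]
            il6[name] = top["IL-6_cyto_mean"].mean()
        assert max(il6, key=il6.get) == "high_concentration"
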