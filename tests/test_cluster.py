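"""Clustering-stage oracles: planted-partition recovery, the
control-anchoring score and its analytic bounds, role mapping on planted
data, and composition bookkeeping."""

import numpy as np
import pytest

from senetrace import cluster as clu
from senetrace import synthetic as syn


def _blobs(rng, k=3, n=100, sep=8.0, dims=4):
    X = np.vstack([rng.normal(i * sep, 1.0, (n, dims)) for i in range(k)])
    labels = np.repeat(np.arange(k), n)
    return X, labels


def planted_control_mixture(rng, k=6, n=80, sep=4.0, dims=6):
    """Well-separated Gaussian mixture (component gaps >= ``sep`` SD) whose
    control component (id 0) is the closest to a neighbor and twice the
    size, making the component count identifiable by control anchoring."""
    centers = np.zeros((k, dims))
    centers[1, 0] = sep                      # control's nearest neighbor
    for i in range(2, k):
        centers[i, i - 1] = 2.5 * sep        # mutually far, all >= sep from 0
    sizes = [2 * n] + [n] * (k - 1)
    X = np.vstack([rng.normal(centers[i], 1.0, (sizes[i], dims))
                   for i in range(k)])
    labels = np.repeat(np.arange(k), sizes)
    return X, labels


class TestKMeansFit:
    def test_k1_single_cluster(self, rng):
        labels, cents = clu.kmeans_fit(rng.normal(size=(30, 3)), 1)
        assert set(labels) == {0}
        assert cents.shape == (1, 3)

    def test_planted_partition_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        X, truth = _blobs(rng)
        labels, _ = clu.kmeans_fit(X, 3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_under_seed(self, rng):
        X, _ = _blobs(rng)
        a, _ = clu.kmeans_fit(X, 3, seed=1)
        b, _ = clu.kmeans_fit(X, 3, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_k_above_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            clu.kmeans_fit(rng.normal(size=(5, 2)), 6)


class TestControlScore:
    def test_bounds_and_relabel_invariance(self, rng):
        X, labels = _blobs(rng)
        control = np.zeros(len(labels), bool)
        control[:100] = True
        s, c = clu.control_score(labels, control)
        assert 0.0 <= s <= 1.0
        relabeled = (labels + 1) % 3
        s2, _ = clu.control_score(relabeled, control)
        assert s == pytest.approx(s2)

    def test_controls_split_across_two_blobs_bounded_by_half(self, rng):
        # analytic bound: if controls split evenly over two distant blobs,
        # no cluster can capture more than half of them -> score <= 0.5
        X, labels = _blobs(rng, k=2, n=100)
        control = np.zeros(200, bool)
        control[:50] = True
        control[100:150] = True
        for k in range(2, 7):
            lab, _ = clu.kmeans_fit(X, k, seed=0)
            s, _ = clu.control_score(lab, control)
            assert s <= 0.5 + 1e-12

    def test_empty_control_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            clu.control_score(np.zeros(10, int), np.zeros(10, bool))


class TestSelectK:
    def test_planted_component_count_recovered(self, rng):
        # controls form one of 5 well-separated blobs.  The planted count is
        # identifiable only if the control blob is the first to be merged
        # (closest pair) and the first to be split (largest), so score(k)
        # peaks uniquely at the true k.
        X, truth = planted_control_mixture(rng, k=5)
        control = truth == 0
        k, model = clu.select_k(X, control, k_range=range(2, 11), seed=0,
                                n_init=5)
        assert k == 5
        assert model.score_trace.loc[
            model.score_trace["k"] == 5, "score"].iloc[0] > 0.95

    def test_trace_matches_brute_force_rescoring(self, rng):
        X, truth = _blobs(rng, k=4, n=50)
        control = truth == 0
        k, model = clu.select_k(X, control, k_range=range(2, 7), seed=3,
                                n_init=5)
        for _, row in model.score_trace.iterrows():
            labels, _ = clu.kmeans_fit(X, int(row["k"]), seed=3, n_init=5)
            s, _ = clu.control_score(labels, control)
            assert s == pytest.approx(row["score"], abs=0)

    def test_degenerate_range(self, rng):
        X, truth = _blobs(rng)
        k, _ = clu.select_k(X, truth == 0, k_range=[3], seed=0, n_init=3)
        assert k == 3

    def test_recall_only_score_available(self, rng):
        X, truth = _blobs(rng, k=3)
        k, model = clu.select_k(X, truth == 0, k_range=range(2, 5), seed=0,
                                n_init=3, score="recall")
        assert (model.score_trace["score"] <= 1.0).all()


class TestMapRoles:
    def test_planted_roles_recovered(self, fitted):
        res, truth = fitted
        agreement = (res.subpop_model.roles() == truth["role"].to_numpy()).mean()
        assert agreement > 0.9
        assert set(res.role_map.values()) == set(syn.ROLES)
        assert res.subpop_model.missing_roles == []

    def test_exactly_one_healthy_cluster(self, fitted):
        res, _ = fitted
        healthy = [c for c, r in res.role_map.items() if r == syn.HEALTHY]
        assert len(healthy) == 1

    def test_largest_area_terminal_is_large_nuclear(self, fitted):
        res, _ = fitted
        cols = res.feature_matrix.columns
        area_i = cols.index("nuclear_area_px")
        terminal_roles = (syn.LARGE_NUCLEAR, syn.HIGH_CONCENTRATION,
                          syn.NONSENESCENT_TERMINAL)
        areas = {r: res.subpop_model.centroids[c, area_i]
                 for c, r in res.role_map.items() if r in terminal_roles}
        assert max(areas, key=areas.get) == syn.LARGE_NUCLEAR

    def test_k2_degenerate_reports_missing_roles(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 6)), rng.normal(6, 1, (100, 6))])
        days = np.repeat([0, 31], 100)
        labels, cents = clu.kmeans_fit(X, 2, seed=0)
        model = clu.SubpopulationModel(k=2, centroids=cents, labels=labels)
        cols = ["nuclear_area_px"] + [f"{m}_nuc_mean" for m in ("p53", "p21")] \
            + [f"f{i}" for i in range(3)]
        clu.map_roles(model, cols, days, marker_panel=("p53", "p21"))
        assert syn.HEALTHY in model.role_map.values()
        assert len(model.missing_roles) >= 2


class TestComposition:
    def test_rows_sum_to_one(self, fitted):
        res, _ = fitted
        np.testing.assert_allclose(res.composition.sum(axis=1), 1.0, atol=1e-12)

    def test_day0_is_healthy(self, fitted):
        res, _ = fitted
        assert res.composition.loc[0, syn.HEALTHY] > 0.95

    def test_day2_senescent_transitional_near_planted(self, fitted):
        res, _ = fitted
        n = 150
        sd = np.sqrt(0.17 * 0.83 / n)
        assert abs(res.composition.loc[2, syn.SENESCENT_TRANSITIONAL] - 0.17) \
            < 3 * sd

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            clu.composition_over_time(np.array([]), {}, np.array([]))
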