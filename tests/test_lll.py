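import math

import numpy as np
import pytest

from conftest import make_neighbor_set, random_feature_matrix
from lazytox.features import EUCLIDEAN, TANIMOTO, FeatureMatrix, distance_matrix
from lazytox.lll import (
    LLLError,
    find_neighbors,
    fit_predict_llr,
    gp_project,
    loo_q2,
    predict_gp,
    predict_sa,
    predict_sr,
    select_n_by_cv,
)

TABLE3_SET1_ACTIVITIES = [4.068, 3.129, 2.687, 3.147, 3.166]
TABLE3_SET1_DISTANCES = [0.543, 0.691, 0.714, 0.720, 0.743]


class TestFindNeighbors:
    def test_identical_reference_compound_comes_first_at_distance_zero(self, rng):
        fm = random_feature_matrix(rng, n=10, kind=EUCLIDEAN)
        y = rng.random(10)
        ns = find_neighbors(fm.vectors[3], fm, y, k=3, query_id="external")
        assert ns.neighbors[0].id == "r003"
        assert ns.neighbors[0].distance == 0.0

    def test_k_larger_than_reference_returns_everything(self, rng):
        fm = random_feature_matrix(rng, n=4)
        ns = find_neighbors(rng.random(8), fm, rng.random(4), k=50)
        assert len(ns) == 4

    def test_matches_exhaustive_sort_oracle(self, rng):
        fm = random_feature_matrix(rng, n=50, kind=EUCLIDEAN)
        y = rng.random(50)
        q = rng.random(8)
        # oracle: brute-force full sort on scalar distances, id tie-break
        dists = [
            (math.sqrt(sum((q[i] - v[i]) ** 2 for i in range(8)) / 8), fm.ids[j], j)
            for j, v in enumerate(fm.vectors)
        ]
        expected = [j for _, _, j in sorted(dists)[:5]]
        ns = find_neighbors(q, fm, y, k=5)
        assert ns.indices == expected
        assert list(ns.distances) == sorted(ns.distances)

    def test_self_excluded_by_id(self, rng):
        fm = random_feature_matrix(rng, n=6)
        ns = find_neighbors(fm.vectors[2], fm, rng.random(6), k=6, query_id="r002")
        assert "r002" not in ns.ids
        assert len(ns) == 5

    def test_tie_break_by_reference_id(self):
        vecs = np.array([[0.5], [0.5], [0.1]])
        fm = FeatureMatrix("DES", EUCLIDEAN, ["zz", "aa", "mm"], vecs)
        ns = find_neighbors(np.array([0.5]), fm, [1.0, 2.0, 3.0], k=2)
        assert ns.ids == ["aa", "zz"]

    def test_empty_reference_errors(self):
        fm = FeatureMatrix("DES", EUCLIDEAN, [], np.zeros((0, 3)))
        with pytest.raises(LLLError):
            find_neighbors(np.zeros(3), fm, [], k=1)


class TestPredictSA:
    def test_mean_of_three(self):
        ns = make_neighbor_set([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        assert predict_sa(ns, 3).value == pytest.approx(2.0)

    def test_n_one_returns_nearest_activity(self):
        ns = make_neighbor_set([0.1, 0.2], [5.5, 1.0])
        assert predict_sa(ns, 1).value == pytest.approx(5.5)

    def test_printed_set1_neighbors(self):
        # mean of the five printed neighbor activities = 3.2394
        ns = make_neighbor_set(TABLE3_SET1_DISTANCES, TABLE3_SET1_ACTIVITIES)
        assert predict_sa(ns, 5).value == pytest.approx(3.2394, abs=1e-4)

    def test_bounded_by_neighbor_range(self, rng):
        for _ in range(50):
            acts = rng.normal(4, 1, 6)
            ns = make_neighbor_set(rng.random(6), acts)
            v = predict_sa(ns, 4).value
            assert acts[:4].min() - 1e-12 <= v <= acts[:4].max() + 1e-12

    def test_empty_neighbors_error(self):
        ns = make_neighbor_set([], [])
        with pytest.raises(LLLError):
            predict_sa(ns, 1)


class TestPredictSR:
    def test_equal_similarities_reduce_to_sa(self):
        ns = make_neighbor_set([0.3, 0.3, 0.3], [1.0, 2.0, 3.0])
        assert predict_sr(ns, 3).value == pytest.approx(predict_sa(ns, 3).value)

    def test_degenerate_weight_takes_similar_neighbor(self):
        ns = make_neighbor_set([0.0, 1.0], [5.0, 9.0])
        assert predict_sr(ns, 2).value == pytest.approx(5.0)

    def test_printed_set1_neighbors_weighted(self):
        # hand oracle: sum((1-d_i)*y_i) / sum(1-d_i) over the printed pairs = 3.32866
        s = [1 - d for d in TABLE3_SET1_DISTANCES]
        expected = sum(si * yi for si, yi in zip(s, TABLE3_SET1_ACTIVITIES)) / sum(s)
        ns = make_neighbor_set(TABLE3_SET1_DISTANCES, TABLE3_SET1_ACTIVITIES)
        got = predict_sr(ns, 5).value
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.3287, abs=1e-4)

    def test_all_zero_weights_error(self):
        ns = make_neighbor_set([1.0, 1.0], [2.0, 3.0])
        with pytest.raises(LLLError):
            predict_sr(ns, 2)

    def test_bounded_by_neighbor_range(self, rng):
        for _ in range(50):
            acts = rng.normal(4, 1, 5)
            ns = make_neighbor_set(rng.random(5) * 0.9, acts)
            v = predict_sr(ns, 5).value
            assert acts.min() - 1e-12 <= v <= acts.max() + 1e-12


class TestGpProject:
    def test_midpoint_symmetry(self):
        # dAC == dBC puts the projection at the middle of AB
        assert gp_project(2.0, 4.0, 1.0, 0.7, 0.7) == pytest.approx(3.0)

    def test_degenerate_edge_returns_average(self):
        assert gp_project(2.0, 4.0, 0.0, 0.3, 0.3) == pytest.approx(3.0)

    def test_right_triangle_projects_onto_vertex_a(self):
        # 3-4-5 right triangle: cos(CAB) = 0, so D == A
        assert gp_project(2.0, 4.0, 4.0, 3.0, 5.0) == pytest.approx(2.0)

    def test_cosine_clamped_for_broken_triangles(self):
        v = gp_project(1.0, 2.0, 0.1, 5.0, 0.1)
        assert math.isfinite(v)


def gp_pairwise_oracle(distances, activities, dnn):
    """Brute-force enumeration of all neighbor pairs with explicit weights."""
    k = len(activities)
    num = den = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            yd = gp_project(activities[i], activities[j], dnn[i][j], distances[i], distances[j])
            w = (1 - distances[i]) * (1 - distances[j])
            num += w * yd
            den += w
    return num / den


class TestPredictGP:
    def test_zero_distance_neighbor_decides_directly(self, rng):
        fm = random_feature_matrix(rng, n=5, kind=EUCLIDEAN)
        ns = find_neighbors(fm.vectors[1], fm, [1, 2, 5.1, 3, 4], k=4, query_id="q")
        # nearest neighbor is r001 itself at distance 0 with activity 2
        res = predict_gp(ns, fm)
        assert res.value == pytest.approx(2.0)
        assert res.neighbor_ids == ["r001"]

    def test_collinear_linear_activity_is_exact(self):
        xs = np.array([[0.1], [0.45], [0.8]])
        y = 2.0 + 3.0 * xs[:, 0]
        fm = FeatureMatrix("DES", EUCLIDEAN, ["a", "b", "c"], xs)
        ns = find_neighbors(np.array([0.3]), fm, y, k=3)
        res = predict_gp(ns, fm)
        assert res.value == pytest.approx(2.0 + 3.0 * 0.3, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_matches_pairwise_enumeration_oracle(self, rng, k):
        for _ in range(20):
            fm = random_feature_matrix(rng, n=k, kind=EUCLIDEAN)
            y = rng.normal(4, 1, k)
            q = rng.random(8)
            ns = find_neighbors(q, fm, y, k=k)
            dnn = distance_matrix(fm.vectors[ns.indices], fm.vectors[ns.indices], EUCLIDEAN)
            expected = gp_pairwise_oracle(list(ns.distances), list(ns.activities), dnn)
            got = predict_gp(ns, fm, k_init=k, k_max=k)
            assert got.value == pytest.approx(expected, rel=1e-10)
            assert got.k_used == k

    def test_two_neighbors_single_pair(self, rng):
        fm = random_feature_matrix(rng, n=2, kind=EUCLIDEAN)
        y = np.array([3.0, 5.0])
        q = rng.random(8)
        ns = find_neighbors(q, fm, y, k=2)
        dnn = distance_matrix(fm.vectors, fm.vectors, EUCLIDEAN)
        expected = gp_project(y[0], y[1], dnn[ns.indices[0], ns.indices[1]],
                              ns.distances[0], ns.distances[1])
        assert predict_gp(ns, fm).value == pytest.approx(expected)

    def test_single_far_neighbor_errors(self):
        fm = FeatureMatrix("DES", EUCLIDEAN, ["a"], np.array([[0.9]]))
        ns = find_neighbors(np.array([0.1]), fm, [2.0], k=1)
        with pytest.raises(LLLError):
            predict_gp(ns, fm)

    def test_never_nan_on_tanimoto_near_degenerate_triangles(self, rng):
        for _ in range(200):
            vecs = (rng.random((6, 12)) < 0.5).astype(np.uint8)
            vecs[:, 0] = 1  # avoid all-zero vectors
            fm = FeatureMatrix("ECFP4", TANIMOTO, [f"r{i}" for i in range(6)], vecs)
            y = rng.normal(4, 1, 6)
            q = (rng.random(12) < 0.5).astype(np.uint8)
            q[0] = 1
            ns = find_neighbors(q, fm, y, k=6)
            res = predict_gp(ns, fm)
            assert math.isfinite(res.value)

    def test_can_extrapolate_beyond_neighbor_range(self):
        # query beyond both neighbors on a line: projection extrapolates
        xs = np.array([[0.2], [0.3]])
        y = np.array([2.0, 3.0])
        fm = FeatureMatrix("DES", EUCLIDEAN, ["a", "b"], xs)
        ns = find_neighbors(np.array([0.6]), fm, y, k=2)
        res = predict_gp(ns, fm)
        assert res.value > y.max()


def _planted_world(rng, n=40, d=5, noise=0.0, slope=3.0):
    X = rng.random((n, d))
    y = slope * X[:, 0] + rng.normal(0, noise, n)
    fm = FeatureMatrix("DES", EUCLIDEAN, [f"r{i:03d}" for i in range(n)], X)
    return fm, y


class TestLLR:
    def test_recovers_planted_linear_signal(self, rng):
        fm, y = _planted_world(rng)
        q = rng.random(5) * 0.8 + 0.1
        res, fit = fit_predict_llr(q, fm, y)
        assert fit.chosen_descriptor == 0
        assert fit.slope == pytest.approx(3.0, abs=1e-9)
        assert res.value == pytest.approx(3.0 * q[0], abs=1e-6)

    def test_query_outside_all_descriptor_ranges_fails(self, rng):
        X = rng.random((30, 4)) * 0.5
        y = X[:, 0] * 2
        fm = FeatureMatrix("DES", EUCLIDEAN, [f"r{i}" for i in range(30)], X)
        res, fit = fit_predict_llr(np.ones(4), fm, y)
        assert res.status == "failed"
        assert fit is None
        assert math.isnan(res.value)

    def test_perfect_line_gives_unit_loo_q2(self, rng):
        fm, y = _planted_world(rng, n=25)
        q = rng.random(5) * 0.8 + 0.1
        _, fit = fit_predict_llr(q, fm, y)
        assert fit.q2 == pytest.approx(1.0, abs=1e-12)

    def test_k_stays_within_bounds(self, rng):
        fm, y = _planted_world(rng, n=60, noise=0.3)
        q = rng.random(5) * 0.8 + 0.1
        res, fit = fit_predict_llr(q, fm, y)
        assert 5 <= fit.k <= 20
        assert res.k_used == fit.k

    def test_neighbor_order_from_other_metric_respected(self, rng):
        fm, y = _planted_world(rng, n=30)
        order = rng.permutation(30)
        q = rng.random(5) * 0.8 + 0.1
        res, fit = fit_predict_llr(q, fm, y, neighbor_order=order)
        assert res.neighbor_ids[0] == fm.ids[order[0]]

    def test_can_extrapolate_beyond_neighbor_activities(self, rng):
        # LLR predicts along a line, so a query at the edge of the descriptor
        # range may land above every neighbor activity
        X = np.linspace(0.1, 0.6, 30).reshape(-1, 1)
        y = 5.0 * X[:, 0]
        fm = FeatureMatrix("DES", EUCLIDEAN, [f"r{i:02d}" for i in range(30)], X)
        res, _ = fit_predict_llr(np.array([0.59]), fm, y)
        near = np.argsort(np.abs(X[:, 0] - 0.59))[: res.k_used]
        assert res.value > 0  # sanity
        assert res.status == "ok"


class TestLooQ2:
    def test_exact_line_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert loo_q2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_three_points_match_manual_refits(self):
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([1.0, 2.0, 2.5])
        # oracle: three explicit two-point refits (a two-point line is exact)
        ss_res = 0.0
        for i in range(3):
            keep = [j for j in range(3) if j != i]
            slope = (y[keep[1]] - y[keep[0]]) / (x[keep[1]] - x[keep[0]])
            intercept = y[keep[0]] - slope * x[keep[0]]
            ss_res += (y[i] - (slope * x[i] + intercept)) ** 2
        expected = 1 - ss_res / np.sum((y - y.mean()) ** 2)
        assert loo_q2(x, y) == pytest.approx(expected, rel=1e-12)

    def test_pure_noise_nonpositive_in_expectation(self):
        r = np.random.default_rng(0)
        vals = [loo_q2(r.random(30), r.normal(size=30)) for _ in range(200)]
        assert np.mean(vals) < 0

    def test_zero_variance_y_rejected(self):
        with pytest.raises(LLLError):
            loo_q2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(LLLError):
            loo_q2([1.0, 2.0], [1.0, 2.0])

    def test_batch_implementation_matches_scalar(self, rng):
        from lazytox.lll import _loo_q2_batch

        X = rng.random((8, 4))
        y = rng.normal(size=8)
        q = X.mean(axis=0)  # inside every column's range
        batch = _loo_q2_batch(X, y, q)
        for j in range(4):
            assert batch[j] == pytest.approx(loo_q2(X[:, j], y), rel=1e-9)


class TestSelectN:
    def test_smooth_noisy_surface_prefers_averaging(self, rng):
        X = rng.random((80, 3))
        y = 0.5 * X[:, 0] + rng.normal(0, 0.5, 80)
        fm = FeatureMatrix("DES", EUCLIDEAN, [f"r{i:03d}" for i in range(80)], X)
        n = select_n_by_cv(fm, y, "SA", n_grid=range(1, 11), seed=3)
        assert n > 1

    def test_tight_clusters_prefer_small_n(self, rng):
        centers = np.array([[0.1] * 4, [0.5] * 4, [0.9] * 4])
        X = np.vstack([c + rng.normal(0, 0.005, (5, 4)) for c in centers])
        y = np.repeat([2.0, 4.5, 7.0], 5)
        fm = FeatureMatrix("DES", EUCLIDEAN, [f"r{i:03d}" for i in range(15)], X)
        n = select_n_by_cv(fm, y, "SA", n_grid=range(1, 13), folds=5, seed=0)
        assert n <= 5  # never worth mixing clusters

    def test_same_seed_is_deterministic(self, rng):
        fm = random_feature_matrix(rng, n=40)
        y = rng.random(40)
        a = select_n_by_cv(fm, y, "SR", seed=11)
        b = select_n_by_cv(fm, y, "SR", seed=11)
        assert a == b

    def test_reference_smaller_than_folds_rejected(self, rng):
        fm = random_feature_matrix(rng, n=5)
        with pytest.raises(LLLError):
            select_n_by_cv(fm, rng.random(5), "SA", folds=10)

    def test_unknown_model_kind_rejected(self, rng):
        fm = random_feature_matrix(rng, n=20)
        with pytest.raises(LLLError):
            select_n_by_cv(fm, rng.random(20), "GP")
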