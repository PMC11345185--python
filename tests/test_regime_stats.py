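import numpy as np
import pytest

from pfr.regime_stats import (BoundaryDiscriminant, IndexPointCloud,
                              ca_impaired, fit_discriminant, group_compare,
                              joint_density, ks2d_two_sample, rank_predictors)


def boundary_cloud(seed, c=0.43, n=4000, jitter=0.05):
    """Points labeled by the true boundary, then jittered in Mx."""
    rng = np.random.default_rng(seed)
    prx_v = rng.uniform(-1, 1, n)
    mx_v = rng.uniform(-1, 1, n)
    lab = np.where(mx_v > c * (1 - prx_v), "pPFR", "nPFR")
    mx_v = np.clip(mx_v + rng.normal(0, jitter, n), -1, 1)
    return IndexPointCloud(np.column_stack([prx_v, mx_v]), lab)


def brute_force_ks2d_stat(a, b):
    """Direct O(n^2) quadrant-count statistic for small samples."""
    best = 0.0
    for ox, oy in np.vstack([a, b]):
        for sx, sy in [(1, 1), (-1, 1), (-1, -1), (1, -1)]:
            fa = np.mean((sx * (a[:, 0] - ox) > 0) & (sy * (a[:, 1] - oy) > 0))
            fb = np.mean((sx * (b[:, 0] - ox) > 0) & (sy * (b[:, 1] - oy) > 0))
            best = max(best, abs(fa - fb))
    return best


class TestKs2d:
    def test_identical_point_sets_give_zero(self):
        a = np.random.default_rng(0).normal(size=(50, 2))
        D, _ = ks2d_two_sample(a, a.copy(), n_perm=100, seed=1)
        assert D == 0.0

    def test_matches_brute_force_statistic(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.normal(0, 1, (25, 2))
            b = rng.normal(0.5, 1, (30, 2))
            D, _ = ks2d_two_sample(a, b, n_perm=100, seed=0)
            assert D == pytest.approx(brute_force_ks2d_stat(a, b), abs=1e-12)

    def test_separated_clouds_maximal_significance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.3, (100, 2))
        b = rng.normal(0, 0.3, (100, 2))
        b[:, 1] += 2.0
        D, p = ks2d_two_sample(a, b, n_perm=999, seed=3)
        assert D > 0.9
        assert p <= 1.0 / 1000

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (60, 2))
        b = rng.normal(0.3, 1.2, (60, 2))
        D1, _ = ks2d_two_sample(a, b, n_perm=100, seed=0)
        a2, b2 = a.copy(), b.copy()
        a2[:, 0] = np.exp(a2[:, 0])  # common monotone map of one coordinate
        b2[:, 0] = np.exp(b2[:, 0])
        D2, _ = ks2d_two_sample(a2, b2, n_perm=100, seed=0)
        assert D1 == pytest.approx(D2, abs=1e-12)

    def test_null_calibration_short(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            a = rng.normal(0, 1, (40, 2))
            b = rng.normal(0, 1, (40, 2))
            _, p = ks2d_two_sample(a, b, n_perm=199,
                                   seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert rejections <= 13  # ~binomial(100, .05) upper tail

    def test_too_few_points_rejected(self):
        a = np.zeros((10, 2))
        with pytest.raises(ValueError, match="20 points"):
            ks2d_two_sample(a, a, n_perm=100)

    def test_too_few_permutations_rejected(self):
        a = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError, match="n_perm"):
            ks2d_two_sample(a, a, n_perm=50)

    def test_asymptotic_p_available(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, (100, 2))
        b = rng.normal(1.5, 1, (100, 2))
        D, p = ks2d_two_sample(a, b, method="asymptotic")
        assert D > 0.4 and p < 0.01


class TestDiscriminant:
    def test_recovery_of_generating_coefficient(self):
        cs = [fit_discriminant(boundary_cloud(s)).c for s in range(8)]
        assert max(abs(c - 0.43) for c in cs) <= 0.05

    def test_perfectly_separable_cloud_scores_one(self):
        cloud = boundary_cloud(0, jitter=0.0)
        d = fit_discriminant(cloud)
        assert d.objective == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_labels_score_near_half(self):
        cloud = boundary_cloud(1)
        rng = np.random.default_rng(2)
        shuffled = IndexPointCloud(cloud.points, rng.permutation(cloud.group))
        d = fit_discriminant(shuffled)
        assert d.objective < 0.55

    def test_ties_break_toward_smaller_c(self):
        # one pPFR point far above every boundary: all c are equally good
        pts = np.array([[0.0, 0.9], [0.0, -0.9]])
        cloud = IndexPointCloud(pts, np.array(["pPFR", "nPFR"]))
        assert fit_discriminant(cloud).c == 0.0

    def test_single_class_rejected(self):
        pts = np.random.default_rng(0).uniform(-1, 1, (50, 2))
        cloud = IndexPointCloud(pts, np.array(["pPFR"] * 50))
        with pytest.raises(ValueError, match="non-pPFR"):
            fit_discriminant(cloud)

    def test_estimator_api(self):
        cloud = boundary_cloud(3)
        est = BoundaryDiscriminant().fit(cloud.points, cloud.group)
        assert abs(est.c_ - 0.43) <= 0.05
        pred = est.predict(np.array([[0.0, 0.9], [0.0, -0.9]]))
        assert list(pred) == [True, False]


class TestCaImpaired:
    @pytest.mark.parametrize("prx_v,mx_v,expected", [
        (0.0, 0.5, True),     # 0.5 > 0.43
        (0.3, 0.3, False),    # 0.43 * 0.7 = 0.301 >= 0.3
        (1.0, 0.01, True),    # boundary collapses to 0 at PRx = 1
    ])
    def test_boundary_cases(self, prx_v, mx_v, expected):
        assert ca_impaired(prx_v, mx_v) is expected

    def test_c_zero_reduces_to_positive_mx_rule(self):
        for mx_v in (-0.5, -1e-9, 1e-9, 0.5):
            assert ca_impaired(0.2, mx_v, c=0.0) == (mx_v > 0)

    def test_prx_zero_reduces_to_mx_threshold(self):
        assert ca_impaired(0.0, 0.44) and not ca_impaired(0.0, 0.42)


class TestJointDensity:
    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(0)
        pts = np.clip(rng.normal(0, 0.3, (600, 2)), -1, 1)
        lab = np.array(["pPFR", "zPFR", "nPFR"] * 200)
        out = joint_density(IndexPointCloud(pts, lab), grid=81)
        cell = (out["grid"][1] - out["grid"][0]) ** 2
        for key in ("pPFR", "zPFR", "nPFR", "non_pPFR"):
            assert out[key].sum() * cell == pytest.approx(1.0, abs=1e-6)

    def test_mode_recovers_cluster_location(self):
        rng = np.random.default_rng(1)
        pts = np.clip(rng.normal([0.4, -0.3], 0.05, (300, 2)), -1, 1)
        lab = np.array(["pPFR"] * 150 + ["zPFR"] * 75 + ["nPFR"] * 75)
        out = joint_density(IndexPointCloud(pts, lab), grid=101)
        i, j = np.unravel_index(np.argmax(out["pPFR"]), out["pPFR"].shape)
        assert out["grid"][i] == pytest.approx(0.4, abs=0.05)
        assert out["grid"][j] == pytest.approx(-0.3, abs=0.05)

    def test_empty_group_rejected(self):
        pts = np.zeros((10, 2))
        cloud = IndexPointCloud(pts, np.array(["pPFR"] * 10))
        with pytest.raises(ValueError, match="empty group"):
            joint_density(cloud)


class TestGroupCompare:
    def test_identical_groups_not_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 300)
        table = group_compare({"ICP": {"pPFR": base, "zPFR": base.copy()}})
        assert not table["ks_significant"].any()
        assert not table["t_significant"].any()

    def test_location_shift_flagged(self):
        rng = np.random.default_rng(1)
        hits_ks = hits_t = 0
        n_sim = 50
        for _ in range(n_sim):
            a = rng.normal(0, 1, 500)
            b = rng.normal(1, 1, 500)
            row = group_compare({"ICP": {"pPFR": a, "nPFR": b}}).iloc[0]
            hits_ks += row["ks_significant"]
            hits_t += row["t_significant"]
        assert hits_ks == n_sim and hits_t == n_sim

    def test_1d_ks_matches_ecdf_gap_oracle(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        b = np.array([2.0, 4.0, 4.0, 6.0])
        row = group_compare({"v": {"pPFR": a, "zPFR": b}}).iloc[0]
        grid = np.unique(np.r_[a, b])
        gap = max(abs(np.mean(a <= g) - np.mean(b <= g)) for g in grid)
        assert row["ks_D"] == pytest.approx(gap, abs=1e-12)

    def test_medians_and_quartiles_reported(self):
        a = np.arange(1.0, 102.0)
        row = group_compare({"v": {"pPFR": a, "zPFR": a + 10}}).iloc[0]
        assert row["median_a"] == 51.0 and row["median_b"] == 61.0
        assert row["q1_a"] == 26.0 and row["q3_a"] == 76.0

    def test_empty_cell_warns_and_omits(self):
        with pytest.warns(UserWarning, match="empty"):
            table = group_compare(
                {"v": {"pPFR": np.arange(10.0), "zPFR": np.array([]),
                       "nPFR": np.arange(10.0) + 1}})
        assert set(table["group_a"]) | set(table["group_b"]) == {"pPFR", "nPFR"}


class TestRankPredictors:
    def planted(self, seed, n=300):
        rng = np.random.default_rng(seed)
        X = {f"x{i}": rng.normal(0, 1, n) for i in range(5)}
        y = 3.0 * X["x0"] + rng.normal(0, 1, n)
        return y, X

    @pytest.mark.parametrize("method", ["ard", "lasso", "ridge"])
    def test_planted_signal_ranked_first(self, method):
        hits = 0
        for seed in range(10):
            y, X = self.planted(seed)
            df = rank_predictors(y, X, method=method, seed=seed)
            hits += df.iloc[0]["predictor"] == "x0"
        assert hits >= 9

    def test_duplicated_columns_equal_under_ridge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 300)
        X = {"a": x, "b": x.copy(), "c": rng.normal(0, 1, 300)}
        y = x + rng.normal(0, 0.5, 300)
        df = rank_predictors(y, X, method="ridge").set_index("predictor")
        assert df.loc["a", "importance"] == pytest.approx(
            df.loc["b", "importance"], rel=1e-6)

    def test_constant_predictor_warned_and_minimal(self):
        rng = np.random.default_rng(1)
        X = {"x0": rng.normal(0, 1, 200), "flat": np.ones(200)}
        y = X["x0"] + rng.normal(0, 0.5, 200)
        with pytest.warns(UserWarning, match="constant"):
            df = rank_predictors(y, X, method="ridge")
        assert df.set_index("predictor").loc["flat", "importance"] == 0.0

    def test_sample_to_predictor_ratio_enforced(self):
        X = {f"x{i}": np.arange(30.0) for i in range(5)}
        with pytest.raises(ValueError, match="samples"):
            rank_predictors(np.arange(30.0), X)

    def test_unknown_method_rejected(self):
        y, X = self.planted(0)
        with pytest.raises(ValueError, match="method"):
            rank_predictors(y, X, method="forest")
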