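"""Validation statistics: correlations, regressions, ICC, DICE, group tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tdcsmap as tm
from conftest import make_field_map


class TestSpatialPearson:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        fm = make_field_map(rng.normal(size=(10, 10, 4)))
        r, p = tm.spatial_pearson(fm, fm)
        assert r == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(1)
        fm = make_field_map(rng.normal(size=(10, 10, 4)))
        neg = make_field_map(-fm.values)
        r, _ = tm.spatial_pearson(fm, neg)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        fm = make_field_map(np.random.default_rng(2).normal(size=(5, 5, 2)))
        flat = make_field_map(np.full((5, 5, 2), 3.0))
        with pytest.raises(ValueError):
            tm.spatial_pearson(fm, flat)

    def test_independent_noise_maps_are_uncorrelated(self):
        """Null calibration: |r| < 0.05 for nearly all 1e4-voxel noise pairs."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            a = make_field_map(rng.normal(size=(25, 20, 20)))
            b = make_field_map(rng.normal(size=(25, 20, 20)))
            r, _ = tm.spatial_pearson(a, b)
            hits += abs(r) < 0.05
        assert hits >= 17  # nominal 95% coverage with binomial slack

    def test_mismatched_grids_rejected(self):
        a = make_field_map(np.zeros((4, 4, 2)))
        b = make_field_map(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError):
            tm.spatial_pearson(a, b)


class TestRangeRegression:
    def test_identity_recovers_unit_slope_all_bounds(self):
        rng = np.random.default_rng(4)
        fm = make_field_map(rng.normal(scale=5, size=(10, 10, 4)))
        table = tm.range_regression(fm, fm, bounds=[np.inf, 10, 5, 1])
        assert np.allclose(table["slope"], 1.0)
        assert np.allclose(table["intercept"], 0.0, atol=1e-12)
        assert np.all(np.diff(table["n_voxels"]) <= 0)

    def test_negation_gives_minus_one_zero(self):
        """The Active vs -Active contract: slope -1.00, intercept 0.00."""
        rng = np.random.default_rng(5)
        fm = make_field_map(rng.normal(scale=5, size=(10, 10, 4)))
        neg = make_field_map(-fm.values)
        table = tm.range_regression(fm, neg, bounds=[np.inf, 5])
        assert np.allclose(table["slope"], -1.0)
        assert np.allclose(table["intercept"], 0.0, atol=1e-12)

    def test_pure_noise_gives_near_zero_slope(self):
        """The Sham contract: measured noise is unrelated to the simulation."""
        rng = np.random.default_rng(6)
        ref = make_field_map(rng.normal(scale=5, size=(20, 20, 10)))
        noise = make_field_map(rng.normal(scale=0.2, size=(20, 20, 10)))
        table = tm.range_regression(noise, ref, bounds=[np.inf])
        assert abs(table["slope"].iloc[0]) < 0.02

    def test_sparse_range_flagged_not_fitted(self):
        ref = make_field_map(np.linspace(5, 50, 32).reshape(8, 4, 1))
        table = tm.range_regression(ref, ref, bounds=[np.inf, 6.0])
        row = table.iloc[1]
        assert not row["computed"] and np.isnan(row["slope"])
        assert row["n_voxels"] < 3

    def test_infinite_bound_equals_plain_ols(self):
        rng = np.random.default_rng(7)
        ref = make_field_map(rng.normal(size=(8, 8, 2)))
        meas = make_field_map(0.8 * ref.values + rng.normal(scale=0.1,
                                                            size=(8, 8, 2)))
        table = tm.range_regression(meas, ref, bounds=[np.inf])
        fit = sps.linregress(ref.values.ravel(), meas.values.ravel())
        assert table["slope"].iloc[0] == pytest.approx(fit.slope)
        assert table["intercept"].iloc[0] == pytest.approx(fit.intercept)

    def test_bound_validation(self):
        fm = make_field_map(np.zeros((4, 4, 2)))
        with pytest.raises(ValueError):
            tm.range_regression(fm, fm, bounds=[1.0, 5.0])  # ascending
        with pytest.raises(ValueError):
            tm.range_regression(fm, fm, bounds=[5.0, -1.0])


class TestPairedMeanFieldTest:
    def test_identical_lists(self):
        diff, p = tm.paired_mean_field_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert diff == 0.0 and p == 1.0

    def test_constant_offset_recovered(self):
        """Simulations lower than measurements by 1.49 nT show up as -1.49."""
        rng = np.random.default_rng(8)
        a = rng.normal(size=7)
        diff, _ = tm.paired_mean_field_test(a, a + 1.49)
        assert diff == pytest.approx(-1.49)

    @pytest.mark.parametrize("seed", [2, 3, 4, 5])
    def test_p_agrees_with_exhaustive_sign_flip_permutation(self, seed):
        """t-test p matches the exact 2^7 sign-flip distribution within 0.01."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0.8, 1.0, size=7)
        b = np.zeros(7)
        _, p_t = tm.paired_mean_field_test(a, b)
        d = a - b
        n_extreme = 0
        t_obs = abs(d.mean() / (d.std(ddof=1) / np.sqrt(7)))
        for signs in product([1.0, -1.0], repeat=7):
            dd = d * np.array(signs)
            t = abs(dd.mean() / (dd.std(ddof=1) / np.sqrt(7)))
            n_extreme += t >= t_obs - 1e-12
        p_perm = n_extreme / 2**7
        assert abs(p_t - p_perm) < 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tm.paired_mean_field_test([1.0], [2.0])
        with pytest.raises(ValueError):
            tm.paired_mean_field_test([1.0, 2.0], [1.0, 2.0, 3.0])


def icc_bruteforce(x, y):
    """Two-way ANOVA ICC(2,1) by explicit loops (independent oracle)."""
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_retest_gives_one(self):
        rng = np.random.default_rng(9)
        fm = make_field_map(rng.normal(size=(10, 10, 2)))
        assert tm.icc(fm, fm) == pytest.approx(1.0)

    def test_equal_noise_sessions_give_half(self):
        """Two sessions = truth + equal noise: reliability 0.5."""
        rng = np.random.default_rng(10)
        truth = rng.normal(size=20000)
        t1 = make_field_map(truth + rng.normal(size=20000))
        t2 = make_field_map(truth + rng.normal(size=20000))
        assert tm.icc(t1, t2) == pytest.approx(0.5, abs=0.03)

    def test_constant_retest_not_positive(self):
        rng = np.random.default_rng(11)
        t1 = make_field_map(rng.normal(size=500))
        t2 = make_field_map(np.full(500, 2.0))
        assert tm.icc(t1, t2) <= 1e-12

    def test_matches_bruteforce_anova_on_small_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=5)
            y = x + rng.normal(scale=0.5, size=5)
            mine = tm.icc(make_field_map(x), make_field_map(y))
            assert mine == pytest.approx(icc_bruteforce(x, y), abs=1e-12)

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        x = rng.normal(size=5)
        y = x + rng.normal(scale=0.5, size=5)
        mine = tm.icc(make_field_map(x), make_field_map(y))
        df = pd.DataFrame({
            "targets": list(range(5)) * 2,
            "raters": ["a"] * 5 + ["b"] * 5,
            "scores": np.concatenate([x, y]),
        })
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        ref = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_rejected(self):
        flat = make_field_map(np.full(10, 1.0))
        with pytest.raises(ValueError):
            tm.icc(flat, flat)


class TestClusterThreshold:
    def test_all_nonsignificant_gives_empty_mask(self):
        assert not tm.threshold_cluster_mask(np.ones((10, 10, 5)), 0.0005).any()

    def test_minimum_cluster_size_filters_small_blobs(self):
        p = np.ones((20, 20, 10))
        p[0:12, 0:10, 0:10] = 1e-6  # 1200 voxels
        p[14:19, 0:10, 0:10] = 1e-6  # 500 voxels
        mask = tm.threshold_cluster_mask(p, 0.0005, min_cluster=1000)
        assert mask[0:12, 0:10, 0:10].all()
        assert not mask[14:19, 0:10, 0:10].any()

    def test_min_cluster_one_is_pure_thresholding(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=(8, 8, 4))
        assert np.array_equal(tm.threshold_cluster_mask(p, 0.3, 1), p < 0.3)

    def test_26_connectivity_joins_diagonal_voxels(self):
        p = np.ones((4, 4, 4))
        p[0, 0, 0] = p[1, 1, 1] = 0.0  # diagonal neighbours
        mask = tm.threshold_cluster_mask(p, 0.5, min_cluster=2)
        assert mask.sum() == 2


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5, 2), bool)
        m[1:3] = True
        assert tm.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5, 2), bool)
        b = np.zeros((5, 5, 2), bool)
        a[0], b[4] = True, True
        assert tm.dice(a, b) == 0.0

    def test_partial_overlap_count_arithmetic(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100] = True
        b[40:140] = True  # |a| = |b| = 100, overlap 60
        assert tm.dice(a.reshape(10, 10, 2), b.reshape(10, 10, 2)) == 0.60

    def test_symmetry(self):
        rng = np.random.default_rng(15)
        a = rng.uniform(size=(6, 6, 3)) > 0.5
        b = rng.uniform(size=(6, 6, 3)) > 0.5
        assert tm.dice(a, b) == tm.dice(b, a)

    def test_both_empty_rejected(self):
        empty = np.zeros((4, 4, 2), bool)
        with pytest.raises(ValueError):
            tm.dice(empty, empty)


class TestComponentCurrentTest:
    def test_one_voxel_map_returns_that_timecourse(self):
        rng = np.random.default_rng(16)
        data = rng.normal(size=(5, 5, 2, 30))
        comp = np.zeros((5, 5, 2))
        comp[2, 3, 1] = 4.0
        tc = tm.extract_component_timecourse(data, comp)
        ref = data[2, 3, 1]
        assert np.allclose(tc / np.linalg.norm(tc), ref / np.linalg.norm(ref))

    def test_anodal_region_without_injection_is_null(self):
        """No injected effect under the anode: group test non-significant."""
        cohort = tm.cohort_fixture(5, seed=21, scan_length=360.0)
        grid = cohort[0][0].grid
        _, anodal, _ = tm.bilateral_field(grid)
        result = tm.component_current_test(
            [s.magnitude_e2 for s, _, _ in cohort],
            anodal.astype(float), cohort[0][2],
        )
        assert result.p > 0.05

    def test_cathodal_injection_detected(self):
        cohort = tm.cohort_fixture(5, seed=22, scan_length=360.0)
        grid = cohort[0][0].grid
        _, _, cathodal = tm.bilateral_field(grid)
        result = tm.component_current_test(
            [s.magnitude_e2 for s, _, _ in cohort],
            cathodal.astype(float), cohort[0][2],
        )
        assert result.p < 0.05
        assert result.mean < 0

    def test_input_validation(self):
        wf = tm.CurrentWaveform(currents=np.zeros(4), tr=2.0)
        data = [np.ones((2, 2, 1, 4))]
        with pytest.raises(ValueError, match="2 subjects"):
            tm.component_current_test(data, np.ones((2, 2, 1)), wf)
        with pytest.raises(ValueError, match="zero"):
            tm.extract_component_timecourse(np.ones((2, 2, 1, 4)),
                                            np.zeros((2, 2, 1)))


class TestVoxelOrderInvariance:
    def test_statistics_invariant_under_reordering(self):
        rng = np.random.default_rng(17)
        n = 600
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(scale=0.5, size=n)
        perm = rng.permutation(n)
        r1, _ = tm.spatial_pearson(make_field_map(x), make_field_map(y))
        r2, _ = tm.spatial_pearson(make_field_map(x[perm]), make_field_map(y[perm]))
        assert r1 == pytest.approx(r2)
        assert tm.icc(make_field_map(x), make_field_map(y)) == pytest.approx(
            tm.icc(make_field_map(x[perm]), make_field_map(y[perm])))
        a = x > 0.3
        b = y > 0.1
        assert tm.dice(a.reshape(-1, 1, 1), b.reshape(-1, 1, 1)) == tm.dice(
            a[perm].reshape(-1, 1, 1), b[perm].reshape(-1, 1, 1))
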