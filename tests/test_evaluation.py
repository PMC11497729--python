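"""MAPE metrics, sliding-window profiles, profile comparison, Spearman CIs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amyloidcast.evaluation import (compare_profiles, mape, regional_mape,
                                    sliding_window_mape, spearman_ci)
from amyloidcast.scale import default_centiloid_map, suvr_to_centiloid


class TestMape:
    def test_zero_at_equality(self):
        v = np.array([1.1, 1.5, 2.0])
        assert mape(v, v) == 0.0

    def test_single_term(self):
        assert mape([1.1], [1.0]) == pytest.approx(10.0)

    def test_two_point_hand_case(self):
        # |2-1|/1 = 100%, |1-2|/2 = 50% -> mean 75%
        assert mape([2.0, 1.0], [1.0, 2.0]) == pytest.approx(75.0)

    def test_non_positive_actual_rejected(self):
        with pytest.raises(ValueError):
            mape([1.0], [0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mape([1.0, 2.0], [1.0])

    @given(st.lists(st.floats(0.5, 5.0), min_size=1, max_size=20))
    def test_non_negative(self, actual):
        a = np.array(actual)
        assert mape(a * 1.07, a) >= 0.0


class TestRegionalMape:
    def test_identical_matrices_are_zero_everywhere(self):
        m = np.random.default_rng(0).uniform(1, 3, (10, 4))
        res = regional_mape(m, m, ["a", "b", "c", "d"])
        assert (res == 0).all()

    def test_uniform_offset_localizes_to_one_region(self):
        actual = np.full((5, 3), 2.0)
        pred = actual.copy()
        pred[:, 1] *= 1.10
        res = regional_mape(pred, actual, ["r0", "r1", "r2"])
        assert res["r1"] == pytest.approx(10.0)
        assert res["r0"] == 0.0 and res["r2"] == 0.0

    def test_columns_match_scalar_mape(self):
        pred = np.array([[2.0, 1.0], [1.0, 2.0]])
        actual = np.array([[1.0, 2.0], [2.0, 1.0]])
        res = regional_mape(pred, actual, ["x", "y"])
        assert res["x"] == pytest.approx(mape(pred[:, 0], actual[:, 0]))
        assert res["y"] == pytest.approx(mape(pred[:, 1], actual[:, 1]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regional_mape(np.ones((3, 2)), np.ones((3, 3)), ["a", "b", "c"])


def _paired_data(n=120, seed=3):
    rng = np.random.default_rng(seed)
    actual = rng.uniform(1.0, 3.3, n)
    predicted = actual * (1 + rng.normal(0, 0.08, n))
    return predicted, actual


class TestSlidingWindow:
    def test_single_spanning_window_equals_global_mape(self):
        predicted, actual = _paired_data()
        cl = suvr_to_centiloid(predicted)
        center = float((cl.min() + cl.max()) / 2)
        profile = sliding_window_mape(predicted, actual, window_width=1000.0,
                                      n_boot=1, centers=[center], seed=0)
        assert profile.mape_point[0] == pytest.approx(mape(predicted, actual))
        assert profile.n_in_window[0] == len(actual)

    def test_same_seed_reproduces_ci_arrays(self):
        predicted, actual = _paired_data()
        p1 = sliding_window_mape(predicted, actual, n_boot=200, seed=5)
        p2 = sliding_window_mape(predicted, actual, n_boot=200, seed=5)
        np.testing.assert_array_equal(p1.ci_low, p2.ci_low)
        np.testing.assert_array_equal(p1.ci_high, p2.ci_high)

    def test_piecewise_error_zones_are_recovered(self):
        # 10% error at ~10 CL, 40% error at ~75 CL
        cmap = default_centiloid_map()
        low = np.full(40, float(cmap.to_suvr(10.0)))
        high = np.full(40, float(cmap.to_suvr(75.0)))
        actual = np.concatenate([low, high])
        predicted = np.concatenate([low * 1.10, high * 1.40])
        profile = sliding_window_mape(predicted, actual, axis="observed",
                                      n_boot=10, seed=0)
        centers = profile.window_centers
        low_idx = np.argmin(np.abs(centers - 10.0))
        high_idx = np.argmin(np.abs(centers - 75.0))
        assert profile.mape_point[low_idx] == pytest.approx(10.0, abs=1e-9)
        assert profile.mape_point[high_idx] == pytest.approx(40.0, abs=1e-9)

    def test_sparse_windows_reported_empty(self):
        predicted, actual = _paired_data(n=30)
        profile = sliding_window_mape(predicted, actual, min_n=1000, n_boot=10, seed=0)
        assert np.isnan(profile.mape_point).all()
        assert (profile.n_in_window >= 0).all()

    def test_point_estimate_lies_inside_ci(self):
        predicted, actual = _paired_data()
        profile = sliding_window_mape(predicted, actual, n_boot=500, seed=2)
        ok = ~np.isnan(profile.mape_point)
        assert np.all(profile.ci_low[ok] <= profile.mape_point[ok] + 1e-9)
        assert np.all(profile.mape_point[ok] <= profile.ci_high[ok] + 1e-9)

    def test_partitioning_windows_average_to_global_mape(self):
        predicted, actual = _paired_data()
        cl = suvr_to_centiloid(predicted)
        width = 25.0
        start = float(np.floor(cl.min())) + width / 2
        centers = np.arange(start, cl.max() + width / 2, width)
        profile = sliding_window_mape(predicted, actual, window_width=width,
                                      centers=centers, min_n=1, n_boot=1, seed=0)
        ok = profile.n_in_window > 0
        weighted = np.nansum(profile.mape_point[ok] * profile.n_in_window[ok])
        assert weighted / profile.n_in_window[ok].sum() == pytest.approx(
            mape(predicted, actual)
        )

    def test_brute_force_oracle_on_tiny_datasets(self):
        # independent recomputation: python loops over windows and resamples
        cmap = default_centiloid_map()
        for seed in (0, 1, 2):
            rng = np.random.default_rng(100 + seed)
            actual = rng.uniform(1.0, 3.0, 25)
            predicted = actual + rng.normal(0, 0.15, 25)
            profile = sliding_window_mape(predicted, actual, window_width=30.0,
                                          step=5.0, min_n=3, n_boot=4000, seed=seed)
            axis = cmap.to_centiloid(predicted)
            err = 100.0 * np.abs(predicted - actual) / actual
            oracle_rng = np.random.default_rng(10_000 + seed)
            for i, c in enumerate(profile.window_centers):
                members = err[(axis >= c - 15.0) & (axis < c + 15.0)]
                if members.size < 3:
                    assert np.isnan(profile.mape_point[i])
                    continue
                assert profile.mape_point[i] == pytest.approx(members.mean())
                boots = [
                    members[oracle_rng.integers(0, members.size, members.size)].mean()
                    for _ in range(4000)
                ]
                assert profile.ci_low[i] == pytest.approx(
                    np.percentile(boots, 2.5), abs=1.5)
                assert profile.ci_high[i] == pytest.approx(
                    np.percentile(boots, 97.5), abs=1.5)

    def test_bootstrap_ci_narrows_with_sample_size(self):
        cmap = default_centiloid_map()
        widths = {}
        for n in (100, 1000):
            rng = np.random.default_rng(42)
            actual = rng.uniform(1.2, 1.6, n)
            predicted = actual * (1 + rng.normal(0, 0.1, n))
            center = float(np.mean(cmap.to_centiloid(predicted)))
            p = sliding_window_mape(predicted, actual, window_width=1000.0,
                                    centers=[center], n_boot=400, seed=7)
            widths[n] = float(p.ci_high[0] - p.ci_low[0])
        assert widths[1000] < widths[100]


class TestCompareProfiles:
    def _profile(self, centers, point, lo, hi):
        from amyloidcast.evaluation import ErrorProfile

        centers = np.asarray(centers, dtype=float)
        return ErrorProfile(centers, 25.0, np.asarray(point, dtype=float),
                            np.asarray(lo, dtype=float), np.asarray(hi, dtype=float),
                            np.full(centers.size, 50), 100, "predicted")

    def test_identical_profiles_have_no_significant_ranges(self):
        p = self._profile([0, 10, 20], [10, 12, 14], [8, 10, 12], [12, 14, 16])
        res = compare_profiles(p, p)
        assert res.a_better_ranges == [] and res.b_better_ranges == []
        assert res.crossover_cl is None

    def test_dominant_profile_covers_the_domain(self):
        a = self._profile([0, 10, 20], [5, 5, 5], [4, 4, 4], [6, 6, 6])
        b = self._profile([0, 10, 20], [20, 20, 20], [18, 18, 18], [22, 22, 22])
        res = compare_profiles(a, b)
        assert res.a_better_ranges == [(0.0, 20.0)]
        assert res.b_better_ranges == []

    def test_known_crossover_is_located(self):
        centers = list(range(0, 70, 10))
        # A significantly better up to 30 CL, then CIs overlap
        a_hi = [6, 6, 6, 6, 15, 15, 15]
        b_lo = [10, 10, 10, 10, 12, 12, 12]
        a = self._profile(centers, [5] * 7, [4] * 7, a_hi)
        b = self._profile(centers, [14] * 7, b_lo, [18] * 7)
        res = compare_profiles(a, b)
        assert res.a_better_ranges == [(0.0, 30.0)]
        assert abs(res.crossover_cl - 30.0) <= 10.0

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(3)
        centers = np.arange(0, 50, 5.0)
        pa = rng.uniform(5, 15, centers.size)
        pb = rng.uniform(5, 15, centers.size)
        a = self._profile(centers, pa, pa - 3, pa + 3)
        b = self._profile(centers, pb, pb - 3, pb + 3)
        ab = compare_profiles(a, b)
        ba = compare_profiles(b, a)
        assert ab.a_better_ranges == ba.b_better_ranges
        assert ab.b_better_ranges == ba.a_better_ranges

    def test_mismatched_grids_rejected(self):
        a = self._profile([0, 10], [5, 5], [4, 4], [6, 6])
        b = self._profile([0, 20], [5, 5], [4, 4], [6, 6])
        with pytest.raises(ValueError):
            compare_profiles(a, b)


class TestSpearman:
    def test_perfect_monotone_association(self):
        x = np.arange(20, dtype=float)
        res = spearman_ci(x, np.exp(x / 5), n_boot=50, seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_perfect_inverse_association(self):
        x = np.arange(15, dtype=float)
        res = spearman_ci(x, -x, n_boot=50, seed=0)
        assert res.rho == pytest.approx(-1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.6, 40)
        r1 = spearman_ci(x, y, n_boot=50, seed=1)
        r2 = spearman_ci(np.exp(x), y, n_boot=50, seed=1)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)
        assert r1.ci_low == pytest.approx(r2.ci_low, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ci(np.ones(20), np.arange(20), n_boot=10, seed=0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_ci(np.arange(5), np.arange(5), n_boot=10, seed=0)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=80)
        y = x + rng.normal(0, 1.0, 80)
        res = spearman_ci(x, y, n_boot=500, seed=2)
        assert res.ci_low <= res.rho <= res.ci_high
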