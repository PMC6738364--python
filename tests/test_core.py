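"""Unit and property tests for the CID/pCID kernel estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from cidnet.core import (CIDEngine, ExpressionMatrix, KernelConfig, cid,
                         estimate_conditional_cdf, estimate_marginal_cdf,
                         pcid)

SMOOTH = KernelConfig()
DEG = KernelConfig(degenerate_limit=True)


class TestMarginalCDF:
    def test_empirical_cdf_at_sample_points(self):
        y = np.array([1.0, 2, 3, 4, 5])
        np.testing.assert_allclose(estimate_marginal_cdf(y, y, DEG),
                                   [0.2, 0.4, 0.6, 0.8, 1.0])

    def test_tails_reach_zero_and_one(self):
        y = np.array([1.0, 2, 3, 4, 5])
        for cfg in (SMOOTH, DEG):
            lo, hi = estimate_marginal_cdf(y, [-1e6, 1e6], cfg)
            assert lo == pytest.approx(0.0, abs=1e-12)
            assert hi == pytest.approx(1.0, abs=1e-12)

    def test_smoothed_close_to_empirical_at_median(self, rng):
        y = rng.normal(size=200)
        smoothed = estimate_marginal_cdf(y, [0.0], SMOOTH)[0]
        empirical = np.mean(y <= 0.0)
        assert abs(smoothed - empirical) < 0.05
        assert abs(smoothed - 0.5) < 0.05

    def test_monotone_and_bounded(self, rng):
        y = rng.normal(size=40)
        grid = np.linspace(-4, 4, 101)
        f = estimate_marginal_cdf(y, grid, SMOOTH)
        assert np.all(np.diff(f) >= 0)
        assert np.all((f >= 0) & (f <= 1))

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="degenerate response"):
            estimate_marginal_cdf(np.ones(10), [0.0], SMOOTH)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            estimate_marginal_cdf(np.array([1.0, 2, 3, 4]), [0.0], SMOOTH)


class TestConditionalCDF:
    def test_constant_predictor_reduces_to_marginal(self, rng):
        y = rng.normal(size=30)
        x = np.full(30, 3.14)
        grid = np.linspace(-2, 2, 11)
        with pytest.warns(UserWarning, match="zero-variance predictor"):
            cond = estimate_conditional_cdf(y, x, grid, x[:5], SMOOTH)
        marg = estimate_marginal_cdf(y, grid, SMOOTH)
        np.testing.assert_allclose(cond, np.tile(marg[:, None], (1, 5)),
                                   atol=1e-12)

    def test_indicator_limit_on_matched_pairs(self):
        y = np.array([1.0, 2, 3, 4, 5])
        cond = estimate_conditional_cdf(y, y, y, y, DEG)
        # weights concentrate on the matching sample j
        expected = (y[None, :] <= y[:, None]).astype(float)
        np.testing.assert_allclose(cond, expected)

    def test_matches_explicit_loop_oracle(self, rng):
        # independent reimplementation: loops + explicit NW weight formula
        n = 100
        x = rng.normal(size=n)
        y = x + rng.normal(0, 0.5, n)
        grid_y = np.quantile(y, [0.25, 0.5, 0.75])
        grid_x = np.array([x.min(), np.median(x), x.max()])
        got = estimate_conditional_cdf(y, x, grid_y, grid_x, SMOOTH)

        def sigma(v):
            iqr = (np.percentile(v, 75) - np.percentile(v, 25)) / 1.349
            return min(np.std(v, ddof=1), iqr) if iqr > 0 else np.std(v,
                                                                      ddof=1)
        hy = 1.06 * sigma(y) * n ** -0.2
        hx = 3.0 * 35 ** -0.2 * sigma(x) * n ** -0.2
        for i, gy in enumerate(grid_y):
            for j, gx in enumerate(grid_x):
                w = np.exp(-0.5 * ((gx - x) / hx) ** 2)
                w = w / w.sum()
                want = float(np.sum(w * ndtr((gy - y) / hy)))
                assert got[i, j] == pytest.approx(want, abs=1e-12)

    def test_conditional_decreases_in_x_for_positive_dependence(self, rng):
        n = 100
        x = rng.normal(size=n)
        y = x + rng.normal(0, 0.3, n)
        med = np.median(y)
        f = estimate_conditional_cdf(y, x, [med], [x.min(), x.max()], SMOOTH)
        assert f[0, 0] > 0.5 > f[0, 1]


class TestCID:
    def test_constant_predictor_gives_zero(self):
        y = np.array([1.0, 2, 3, 4, 5])
        with pytest.warns(UserWarning):
            assert cid(y, np.ones(5), SMOOTH).value == pytest.approx(0.0,
                                                                     abs=1e-12)
        assert cid(y, np.ones(5), DEG).value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("x", [np.arange(1.0, 6), np.arange(5.0, 0, -1)])
    def test_monotone_pairing_is_exactly_one_in_limit(self, x):
        # hand oracle: numerator 4, denominator 0.8 -> (1/5)(4/0.8) = 1
        y = np.array([1.0, 2, 3, 4, 5])
        assert cid(y, x, DEG).value == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=20,
                    unique=True),
           st.sampled_from(["exp", "cube", "neg"]))
    def test_any_strictly_monotone_bijection_gives_one(self, vals, form):
        y = np.asarray(vals, dtype=float)
        x = {"exp": np.exp(y / 50.0), "cube": y ** 3, "neg": -y}[form]
        assert cid(y, x, DEG).value == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_limit_bounded_by_one(self, rng):
        y = rng.normal(size=25)
        x = rng.normal(size=25)
        v = cid(y, x, DEG).value
        assert 0.0 <= v <= 1.0 + 1e-12

    def test_asymmetric_for_noninjective_dependence(self):
        # y is a function of x but not vice versa: knowing x pins y down
        x = np.array([-2.0, -1.5, -1, -0.5, 0.5, 1, 1.5, 2])
        y = np.abs(x)
        fwd = cid(y, x, DEG).value
        rev = cid(x, y, DEG).value
        assert fwd == pytest.approx(1.0, abs=1e-12)
        assert rev < fwd

    def test_independence_null_is_small(self, rng):
        vals = []
        for _ in range(500):
            y = rng.normal(size=50)
            x = rng.normal(size=50)
            vals.append(cid(y, x, SMOOTH).value)
        assert np.mean(vals) <= 0.06

    def test_fast_path_matches_direct_double_sum(self, rng):
        # oracle: the definition evaluated literally from the two CDFs
        n = 40
        y = rng.normal(size=n)
        x = (y + rng.normal(0, 0.5, n)).reshape(-1, 1)
        got = cid(y, x, SMOOTH).value
        fy = estimate_marginal_cdf(y, y, SMOOTH)
        fcond = estimate_conditional_cdf(y, x, y, x, SMOOTH)
        num = float(((fcond - fy[:, None]) ** 2).sum())
        den = float((fy * (1 - fy)).sum())
        assert got == pytest.approx(num / (n * den), abs=1e-12)

    def test_sample_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="sample count"):
            cid(rng.normal(size=10), rng.normal(size=9))

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError, match="degenerate response"):
            cid(np.ones(10), np.arange(10.0))


class TestPCID:
    def test_zero_baseline_reduces_to_joint_cid(self, rng):
        y = rng.normal(size=30)
        x2 = y + rng.normal(0, 0.5, 30)
        x1 = np.full(30, 2.0)  # constant: CID(y|x1) = 0
        with pytest.warns(UserWarning):
            got = pcid(y, x2, x1, SMOOTH).value
        with pytest.warns(UserWarning):
            joint = cid(y, np.column_stack([x2, x1]), SMOOTH).value
        assert got == pytest.approx(joint, abs=1e-12)

    def test_duplicate_predictor_adds_nothing_in_limit(self, rng):
        # x1 has ties so the exact-match conditioning does not saturate
        y = rng.normal(size=20)
        x1 = np.repeat([0.0, 1.0, 2.0, 3.0], 5)
        assert pcid(y, x1, x1, DEG).value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_recursion_identity(self, rng, k):
        # oracle: re-evaluate the recursion from two independent cid calls
        n = 50
        y = rng.normal(size=n)
        x1 = rng.normal(size=(n, k))
        x2 = y + rng.normal(0, 1.0, n)
        got = pcid(y, x2, x1, SMOOTH).value
        joint = cid(y, np.column_stack([x2, x1]), SMOOTH).value
        base = cid(y, x1, SMOOTH).value
        assert got == pytest.approx((joint - base) / (1 - base), abs=1e-12)

    def test_may_be_negative(self, rng):
        # an irrelevant new predictor dilutes an informative conditioning
        # set, so the increment can dip below zero
        vals = []
        for _ in range(30):
            x1 = rng.normal(size=25)
            y = x1 + rng.normal(0, 0.3, 25)
            x2 = rng.normal(size=25)
            vals.append(pcid(y, x2, x1, SMOOTH).value)
        assert min(vals) < 0

    def test_saturated_conditioning_set_rejected(self):
        y = np.array([1.0, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="saturated"):
            pcid(y, np.array([2.0, 1, 4, 3, 5]), y, DEG)


class TestEngine:
    def test_matches_functional_api(self, small_matrix):
        eng = CIDEngine(small_matrix)
        y = small_matrix.row("P1")
        x = small_matrix.row("P2")
        assert eng.cid_value("P1", "P2") == pytest.approx(
            cid(y, x, SMOOTH).value, abs=1e-14)
        x1 = small_matrix.row("P3")
        want = pcid(y, x, x1, SMOOTH).value
        assert eng.pcid_value("P1", "P2", ("P3",)) == pytest.approx(
            want, abs=1e-14)

    def test_identity_permutation_matches_observed(self, small_matrix):
        eng = CIDEngine(small_matrix)
        ident = np.arange(small_matrix.N)
        assert eng.cid_value("P1", "P2", perm=ident) == pytest.approx(
            eng.cid_value("P1", "P2"), abs=1e-14)

    def test_permuted_statistic_matches_permuted_data(self, small_matrix,
                                                      rng):
        # permuting the response rows of the matrix must equal the fast path
        perm = rng.permutation(small_matrix.N)
        fast = CIDEngine(small_matrix).cid_value("P1", "P2", perm=perm)
        y = small_matrix.row("P1")[perm]
        direct = cid(y, small_matrix.row("P2"), SMOOTH).value
        assert fast == pytest.approx(direct, abs=1e-12)

    def test_response_equal_predictor_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="distinct"):
            CIDEngine(small_matrix).cid_value("P1", "P1")


class TestExpressionMatrix:
    def test_drops_rows_with_missing_values(self):
        vals = np.ones((2, 6))
        vals[0] += np.arange(6)
        vals[1, 3] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            m = ExpressionMatrix(["a", "b"], [f"s{i}" for i in range(6)],
                                 vals)
        assert m.probe_ids == ["a"]

    def test_duplicate_probe_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(["a", "a"], ["s1", "s2"], np.ones((2, 2)))

    def test_dataframe_round_trip(self, small_matrix):
        back = ExpressionMatrix.from_dataframe(small_matrix.to_dataframe())
        np.testing.assert_array_equal(back.values, small_matrix.values)
        assert back.probe_ids == small_matrix.probe_ids
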