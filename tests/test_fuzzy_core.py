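"""Fuzzy numbers: δ-cuts, membership reconstruction, interval arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzykld.fuzzy_core import (
    DEFAULT_DELTA_GRID,
    FuzzyInterval,
    FuzzyNumber,
    SidedDescription,
    delta_cut,
    expectations,
    fuzzy_add,
    fuzzy_correlation,
    fuzzy_mean,
    fuzzy_multiply,
    membership_from_cuts,
)

from conftest import random_fuzzy_interval, supmin_binary_op, supmin_cut


class TestDeltaCut:
    def test_triangular_midlevel(self):
        t = FuzzyInterval.triangular(-1, 0, 1)
        np.testing.assert_allclose(delta_cut(t, 0.5), [[-0.5, 0.5]])

    def test_triangular_peak(self):
        t = FuzzyInterval.triangular(-1, 0, 1)
        np.testing.assert_allclose(delta_cut(t, 1.0), [[0.0, 0.0]])

    def test_crisp_identity(self):
        c = FuzzyInterval.crisp(3.7)
        for d in (0.05, 0.31, 1.0):
            np.testing.assert_allclose(delta_cut(c, d), [[3.7, 3.7]])

    def test_off_grid_level_uses_next_level_up(self):
        t = FuzzyInterval.triangular(0, 1, 2)
        # 0.52 is between grid levels 0.50 and 0.55 -> cut at 0.55
        np.testing.assert_allclose(delta_cut(t, 0.52), delta_cut(t, 0.55))

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_domain_error(self, bad):
        t = FuzzyInterval.triangular(-1, 0, 1)
        with pytest.raises(ValueError):
            delta_cut(t, bad)


class TestMembership:
    def test_triangular_value(self):
        t = FuzzyInterval.triangular(-1, 0, 1)
        assert membership_from_cuts(t, 0.5) == pytest.approx(0.5, abs=0.051)

    def test_outside_support_zero(self):
        t = FuzzyInterval.triangular(-1, 0, 1)
        assert membership_from_cuts(t, 2.5) == 0.0

    def test_peak_value_one(self):
        t = FuzzyInterval.triangular(-1, 0, 1)
        assert membership_from_cuts(t, 0.0) == 1.0

    def test_cut_membership_round_trip(self, rng):
        """Cutting the reconstructed membership reproduces the stored cuts."""
        x = random_fuzzy_interval(rng)
        ts = np.linspace(x.support[0], x.support[1], 400)
        mem = np.array([x.membership(t) for t in ts])
        for delta, cut in zip(x.delta_grid, x.cuts):
            inside = mem >= delta - 1e-12
            lo, hi = ts[inside].min(), ts[inside].max()
            step = ts[1] - ts[0]
            assert lo == pytest.approx(cut[0, 0], abs=step + 1e-9)
            assert hi == pytest.approx(cut[0, 1], abs=step + 1e-9)


class TestValidation:
    def test_non_nesting_rejected(self):
        grid = [0.5, 1.0]
        with pytest.raises(ValueError, match="nest"):
            FuzzyNumber(grid, [[[0, 1]], [[2, 3]]])

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            FuzzyNumber([0.5, 1.0], [[[1, 0]], [[0.5, 0.5]]])

    def test_multi_interval_rejected_for_interval_type(self):
        with pytest.raises(ValueError, match="exactly one"):
            FuzzyInterval([0.5, 1.0], [[[0, 1], [2, 3]], [[0.2, 0.4]]])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_random_memberships_produce_nested_cuts(self, seed):
        """From-membership construction always yields nested δ-cuts."""
        rng = np.random.default_rng(seed)
        # random bimodal bump membership, peak forced to 1
        c1, c2 = np.sort(rng.uniform(-3, 3, size=2))
        w1, w2 = rng.uniform(0.3, 1.5, size=2)

        def mem(x):
            v = np.maximum(np.exp(-((x - c1) / w1) ** 2),
                           0.8 * np.exp(-((x - c2) / w2) ** 2))
            return v / 1.0

        x = FuzzyNumber.from_membership(mem, (-6, 6))
        # _validate ran in the constructor; re-check the invariant directly
        for i in range(x.n_levels - 1):
            outer = x.cuts[i]
            for a, b in x.cuts[i + 1]:
                assert any(a >= c - 1e-9 and b <= d + 1e-9 for c, d in outer)


class TestArithmetic:
    def test_add_endpoints(self):
        g = DEFAULT_DELTA_GRID
        n = len(g)
        a = FuzzyInterval.from_bounds(g, np.full(n, 1.0), np.full(n, 2.0))
        b = FuzzyInterval.from_bounds(g, np.full(n, 3.0), np.full(n, 4.0))
        out = fuzzy_add(a, b)
        for d in g:
            np.testing.assert_allclose(out.delta_cut(d), [[4.0, 6.0]])

    def test_add_crisp_zero_identity(self, rng):
        x = random_fuzzy_interval(rng)
        out = fuzzy_add(x, FuzzyInterval.crisp(0.0))
        np.testing.assert_allclose(out.lowers, x.lowers)
        np.testing.assert_allclose(out.uppers, x.uppers)

    def test_add_commutes(self, rng):
        x, y = random_fuzzy_interval(rng), random_fuzzy_interval(rng)
        xy, yx = fuzzy_add(x, y), fuzzy_add(y, x)
        np.testing.assert_allclose(xy.lowers, yx.lowers)
        np.testing.assert_allclose(xy.uppers, yx.uppers)

    def test_multiply_mixed_signs(self):
        g = DEFAULT_DELTA_GRID
        n = len(g)
        a = FuzzyInterval.from_bounds(g, np.full(n, -1.0), np.full(n, 2.0))
        b = FuzzyInterval.from_bounds(g, np.full(n, 3.0), np.full(n, 4.0))
        np.testing.assert_allclose(fuzzy_multiply(a, b).delta_cut(0.5), [[-4.0, 8.0]])

    def test_multiply_crisp_one_identity(self, rng):
        x = random_fuzzy_interval(rng)
        out = fuzzy_multiply(x, FuzzyInterval.crisp(1.0))
        np.testing.assert_allclose(out.lowers, x.lowers)
        np.testing.assert_allclose(out.uppers, x.uppers)

    def test_multiply_square_brute_force(self):
        """[1,2]⊗[1,2] equals the brute-force extrema over the cut box."""
        g = DEFAULT_DELTA_GRID
        n = len(g)
        a = FuzzyInterval.from_bounds(g, np.full(n, 1.0), np.full(n, 2.0))
        xs = np.linspace(1, 2, 100)
        prods = np.outer(xs, xs)
        np.testing.assert_allclose(fuzzy_multiply(a, a).delta_cut(0.5),
                                   [[prods.min(), prods.max()]])
        assert prods.min() == pytest.approx(1.0)
        assert prods.max() == pytest.approx(4.0)

    def test_mean_two_intervals(self):
        g = DEFAULT_DELTA_GRID
        n = len(g)
        a = FuzzyInterval.from_bounds(g, np.full(n, 0.0), np.full(n, 1.0))
        b = FuzzyInterval.from_bounds(g, np.full(n, 2.0), np.full(n, 3.0))
        np.testing.assert_allclose(fuzzy_mean([a, b]).delta_cut(1.0), [[1.0, 2.0]])

    def test_mean_single_and_identical(self, rng):
        x = random_fuzzy_interval(rng)
        for xs in ([x], [x, x, x]):
            out = fuzzy_mean(xs)
            np.testing.assert_allclose(out.lowers, x.lowers)
            np.testing.assert_allclose(out.uppers, x.uppers)

    def test_mean_empty_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_mean([])


class TestSupMinOracle:
    """Cut arithmetic agrees with the sup–min extension on a dense grid."""

    @pytest.mark.parametrize("seed", range(5))
    def test_sum_and_product_match_supmin(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_fuzzy_interval(rng), random_fuzzy_interval(rng)
        for opname, op, result in (
            ("add", np.add, fuzzy_add(x, y)),
            ("mul", np.multiply, fuzzy_multiply(x, y)),
        ):
            zz, mm = supmin_binary_op(x, y, op)
            span = zz.max() - zz.min()
            step = span / 199 * 2 + 1e-9  # one grid step per input axis
            for delta in (0.1, 0.5, 0.95):
                lo, hi = supmin_cut(zz, mm, delta)
                (a, b), = result.delta_cut(delta)
                assert a == pytest.approx(lo, abs=step), opname
                assert b == pytest.approx(hi, abs=step), opname


class TestExpectations:
    def test_triangular_closed_form(self):
        sd = SidedDescription(0, 1, 1, 2, f=lambda t: t, g=lambda t: 2 - t)
        lo, hi = expectations(sd)
        assert lo == pytest.approx(0.5)
        assert hi == pytest.approx(1.5)

    def test_crisp_degenerate(self):
        lo, hi = expectations(SidedDescription.crisp(4.2))
        assert lo == hi == 4.2

    def test_symmetric_midpoint_is_centre(self):
        """Quadrature on a Gaussian-shaped membership centred at m."""
        m, s = 1.7, 0.6
        f = lambda t: np.exp(-0.5 * ((t - m) / s) ** 2)
        sd = SidedDescription(m - 4 * s, m, m, m + 4 * s, f=f, g=f)
        lo, hi = expectations(sd)
        assert 0.5 * (lo + hi) == pytest.approx(m, abs=1e-8)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        x = SidedDescription.triangular(0, 1, 2)
        _, rho = fuzzy_correlation(x, x)
        assert rho == pytest.approx(1.0)

    def test_correlation_arithmetic(self):
        # rectangular memberships with expectations (0.5, 1.5) and (1, 3)
        x = SidedDescription(0.5, 0.5, 1.5, 1.5)
        y = SidedDescription(1.0, 1.0, 3.0, 3.0)
        c, _ = fuzzy_correlation(x, y)
        assert c == pytest.approx(0.5 * 1.0 + 1.5 * 3.0)

    def test_symmetry(self):
        x = SidedDescription.triangular(0, 1, 2)
        y = SidedDescription.triangular(1, 2, 5)
        assert fuzzy_correlation(x, y)[1] == pytest.approx(
            fuzzy_correlation(y, x)[1])

    def test_zero_self_correlation_rejected(self):
        z = SidedDescription.crisp(0.0)
        y = SidedDescription.triangular(1, 2, 3)
        with pytest.raises(ZeroDivisionError):
            fuzzy_correlation(z, y)


class TestSerialization:
    def test_json_round_trip_lossless(self, rng):
        x = random_fuzzy_interval(rng)
        y = FuzzyNumber.from_json(x.to_json())
        assert np.array_equal(x.delta_grid, y.delta_grid)
        for a, b in zip(x.cuts, y.cuts):
            np.testing.assert_array_equal(a, b)
        assert x.support == y.support

    def test_multi_interval_round_trip(self):
        x = FuzzyNumber([0.5, 1.0], [[[0, 1], [2, 3]], [[0.5, 0.8]]])
        y = FuzzyNumber.from_json(x.to_json())
        assert x == y
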