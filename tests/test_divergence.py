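"""Classical, extended and fuzzy extended Kullback-Leibler divergences."""

import numpy as np
import pytest

from fuzzykld.divergence import (
    EmpiricalPartition,
    FuzzyParametricDistribution,
    SupportMismatchError,
    build_partition,
    extended_kld,
    fuzzy_extended_kld,
    kld_continuous,
)
from fuzzykld.fuzzy_core import FuzzyInterval
from fuzzykld.parametric import make_distribution


def gaussian_kld(m1, s1, m2, s2):
    """Closed-form D(N(m1, s1^2) || N(m2, s2^2))."""
    return (np.log(s2 / s1) + (s1 ** 2 + (m1 - m2) ** 2) / (2 * s2 ** 2) - 0.5)


class TestBuildPartition:
    def test_sorted_breakpoints_and_probs(self):
        p = build_partition([3, 1, 2], epsilon=0.5)
        np.testing.assert_allclose(p.breakpoints, [0.5, 1, 2, 3])
        np.testing.assert_allclose(p.probabilities, [1 / 3] * 3)

    def test_tie_merge(self):
        p = build_partition([1, 1, 2])
        assert len(p.counts) == 2
        np.testing.assert_allclose(p.probabilities, [2 / 3, 1 / 3])

    def test_probabilities_sum_to_one(self, rng):
        p = build_partition(rng.normal(size=500))
        assert p.probabilities.sum() == pytest.approx(1.0)

    def test_default_epsilon_is_hundredth_sd(self, rng):
        x = rng.normal(size=100)
        p = build_partition(x)
        assert p.epsilon == pytest.approx(np.std(x, ddof=1) / 100)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            build_partition([1.0])


class TestContinuousKLD:
    def test_identical_gaussians_zero(self):
        d = make_distribution("normal", {"mean": 0, "sd": 1})
        assert kld_continuous(d, d) == pytest.approx(0.0, abs=1e-9)

    def test_mean_shift_closed_form(self):
        f = make_distribution("normal", {"mean": 0.5, "sd": 1})
        g = make_distribution("normal", {"mean": 0.0, "sd": 1})
        assert kld_continuous(f, g) == pytest.approx(0.125, abs=1e-6)

    def test_twenty_random_gaussian_pairs_match_closed_form(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            m1, m2 = rng.uniform(-3, 3, 2)
            s1, s2 = rng.uniform(0.3, 3, 2)
            f = make_distribution("normal", {"mean": m1, "sd": s1})
            g = make_distribution("normal", {"mean": m2, "sd": s2})
            assert kld_continuous(f, g) == pytest.approx(
                gaussian_kld(m1, s1, m2, s2), abs=1e-6)

    def test_asymmetry(self):
        f = make_distribution("normal", {"mean": 0, "sd": 1})
        g = make_distribution("normal", {"mean": 1, "sd": 2})
        assert kld_continuous(f, g) != pytest.approx(kld_continuous(g, f),
                                                     abs=1e-3)

    def test_support_mismatch_signalled(self):
        f = make_distribution("normal", {"mean": 0, "sd": 1})
        g = make_distribution("uniform", {"lower": -1, "upper": 1})
        with pytest.raises(SupportMismatchError):
            kld_continuous(f, g)


class TestExtendedKLD:
    def test_zero_when_probabilities_coincide(self):
        # uniform(0,3) against sample {1,2,3} with eps=1: both (1/3,1/3,1/3)
        d = make_distribution("uniform", {"lower": 0, "upper": 3})
        part = build_partition([1.0, 2.0, 3.0], epsilon=1.0)
        assert extended_kld(d, part) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_negative_value(self):
        # uniform(0,4): each interval has model mass 1/4 -> sum is negative
        d = make_distribution("uniform", {"lower": 0, "upper": 4})
        part = build_partition([1.0, 2.0, 3.0], epsilon=1.0)
        expected = 3 * 0.25 * np.log(0.25 / (1 / 3))
        assert extended_kld(d, part) == pytest.approx(expected, abs=1e-12)

    def test_normalized_mode_non_negative(self):
        d = make_distribution("uniform", {"lower": 0, "upper": 4})
        part = build_partition([1.0, 2.0, 3.0], epsilon=1.0)
        assert extended_kld(d, part, normalize_partition_mass=True) >= 0.0

    def test_empirical_direction_is_log_likelihood_ranking(self, rng):
        """Empirical-weighted divergence orders models like the sample
        log-likelihood of the interval counts."""
        x = rng.normal(1.0, 1.0, size=400)
        part = build_partition(x)
        models = [make_distribution("normal", {"mean": m, "sd": 1.0})
                  for m in (0.0, 0.8, 1.0, 1.3)]
        divs = [extended_kld(m, part, direction="empirical") for m in models]
        loglik = []
        for m in models:
            p_f = np.maximum(np.diff(m.cdf(part.breakpoints)), 1e-300)
            loglik.append(float((part.counts * np.log(p_f)).sum()))
        assert np.argsort(divs).tolist() == np.argsort(loglik)[::-1].tolist()

    def test_vanishes_for_large_true_samples(self):
        """Fit-to-own-sample divergence decreases as n grows."""
        d = make_distribution("normal", {"mean": 0, "sd": 1})
        vals = [abs(extended_kld(d, build_partition(d.sample(n, seed=5))))
                for n in (100, 1000, 10_000)]
        assert vals[2] < vals[0]


def fuzzy_normal(mean_cut, sd_cut, delta_grid=None):
    grid = np.round(np.arange(1, 11) / 10, 10) if delta_grid is None else delta_grid
    n = len(grid)

    def tri(lo, hi):
        mid = 0.5 * (lo + hi)
        return FuzzyInterval.from_bounds(
            grid, lo + (mid - lo) * grid, hi - (hi - mid) * grid,
            support=(lo, hi))

    return FuzzyParametricDistribution("normal", {
        "mean": tri(*mean_cut), "sd": tri(*sd_cut)})


class TestFuzzyExtendedKLD:
    def test_all_crisp_degenerates_to_point(self, rng):
        f = make_distribution("normal", {"mean": 0.3, "sd": 1.1})
        part = build_partition(rng.normal(size=200))
        v = extended_kld(f, part)
        fd = fuzzy_extended_kld(f, part, grid_res=5)
        np.testing.assert_allclose(fd.lowers, v)
        np.testing.assert_allclose(fd.uppers, v)

    def test_fuzzy_mean_against_crisp_standard_normal(self):
        """N(mu*, 1) with mu* triangular on [-0.5, 0.5] vs crisp N(0, 1):
        the widest cut approaches [0, 0.5^2/2] of the closed form."""
        grid = np.round(np.arange(1, 11) / 10, 10)
        mu = FuzzyInterval.triangular(-0.5, 0.0, 0.5, delta_grid=grid)
        f = FuzzyParametricDistribution("normal", {"mean": mu, "sd": 1.0})
        g = make_distribution("normal", {"mean": 0, "sd": 1})
        fd = fuzzy_extended_kld(f, g, grid_res=11)
        # delta=0.1 cut of mu is [-0.45, 0.45]
        assert fd.lowers[0] == pytest.approx(0.0, abs=1e-6)
        assert fd.uppers[0] == pytest.approx(0.45 ** 2 / 2, abs=1e-4)
        assert fd.lowers[-1] == pytest.approx(0.0, abs=1e-9)
        assert fd.uppers[-1] == pytest.approx(0.0, abs=1e-9)

    def test_cuts_nest_and_nonnegative_endpoints_in_normalized_mode(self, rng):
        x = rng.normal(0.5, 1.2, size=300)
        part = build_partition(x)
        f = fuzzy_normal((0.0, 1.0), (0.8, 1.6))
        fd = fuzzy_extended_kld(f, part, grid_res=7,
                                normalize_partition_mass=True)
        assert np.all(np.diff(fd.lowers) >= -1e-12)
        assert np.all(np.diff(fd.uppers) <= 1e-12)
        assert np.all(fd.lowers >= 0.0)
        assert np.all(fd.uppers >= fd.lowers - 1e-12)

    @pytest.mark.parametrize("two_params", [False, True])
    def test_matches_denser_brute_force_grid(self, rng, two_params):
        """Grid + refinement endpoints agree with a 10x denser grid search."""
        x = rng.normal(0.2, 1.0, size=150)
        part = build_partition(x)
        grid = np.array([0.25, 0.5, 0.75, 1.0])
        mean = FuzzyInterval.triangular(-0.2, 0.3, 0.8, delta_grid=grid)
        sd = (FuzzyInterval.triangular(0.7, 1.0, 1.4, delta_grid=grid)
              if two_params else 1.0)
        f = FuzzyParametricDistribution("normal", {"mean": mean, "sd": sd})
        fd = fuzzy_extended_kld(f, part, grid_res=9, refine=True)

        def brute(delta):
            box = f.param_box(delta)
            free = [b for b in box if b[1] > b[0]]
            axes = [np.linspace(lo, hi, 90) for lo, hi in free]
            vals = []
            if axes:
                mesh = np.meshgrid(*axes, indexing="ij")
                pts = np.stack([m.ravel() for m in mesh], axis=1)
            else:
                pts = np.zeros((1, 0))
            for th in pts:
                params = {}
                i = 0
                for name, (lo, hi) in zip(("mean", "sd"), box):
                    if hi > lo:
                        params[name] = float(th[i])
                        i += 1
                    else:
                        params[name] = lo
                d = make_distribution("normal", params)
                vals.append(extended_kld(d, part))
            return min(vals), max(vals)

        for i, delta in enumerate(grid):
            lo, hi = brute(float(delta))
            assert fd.lowers[i] == pytest.approx(lo, abs=2e-3)
            assert fd.uppers[i] == pytest.approx(hi, abs=2e-3)

    def test_grid_res_validation(self, rng):
        part = build_partition(rng.normal(size=50))
        f = fuzzy_normal((0, 1), (0.5, 1.5))
        with pytest.raises(ValueError):
            fuzzy_extended_kld(f, part, grid_res=1)

    def test_defuzzify_midpoint_of_crisp(self, rng):
        f = make_distribution("normal", {"mean": 0, "sd": 1})
        part = build_partition(rng.normal(size=100))
        fd = fuzzy_extended_kld(f, part, grid_res=3)
        assert fd.defuzzify() == pytest.approx(extended_kld(f, part))

    def test_serialization_round_trip(self):
        f = fuzzy_normal((0, 1), (0.5, 1.5))
        d = FuzzyParametricDistribution.from_dict(f.to_dict())
        assert d.family == "normal"
        for k in ("mean", "sd"):
            np.testing.assert_array_equal(d.params[k].lowers, f.params[k].lowers)
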