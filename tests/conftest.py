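import numpy as np
import pytest

from fuzzykld.fuzzy_core import DEFAULT_DELTA_GRID, FuzzyInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fuzzy_interval(rng, delta_grid=None) -> FuzzyInterval:
    """A random trapezoid-like fuzzy interval with monotone side curvature."""
    grid = DEFAULT_DELTA_GRID if delta_grid is None else delta_grid
    a = rng.uniform(-5, 5)
    core_lo = a + rng.uniform(0.1, 3)
    core_hi = core_lo + rng.uniform(0, 2)
    b = core_hi + rng.uniform(0.1, 3)
    pl, pr = rng.uniform(0.5, 2, size=2)  # side shape exponents
    lowers = a + (core_lo - a) * np.asarray(grid) ** pl
    uppers = b - (b - core_hi) * np.asarray(grid) ** pr
    return FuzzyInterval.from_bounds(grid, lowers, uppers, support=(a, b))


def supmin_binary_op(x, y, op, n_points: int = 200):
    """Sup–min extension of a binary operation, on discretized memberships.

    Returns (z_grid, membership) with the operation applied over the
    n_points × n_points product grid of the two supports.
    """
    xs = np.linspace(x.support[0], x.support[1], n_points)
    ys = np.linspace(y.support[0], y.support[1], n_points)
    mx = np.array([x.membership(t) for t in xs])
    my = np.array([y.membership(t) for t in ys])
    zz = op(xs[:, None], ys[None, :]).ravel()
    mm = np.minimum(mx[:, None], np.broadcast_to(my[None, :], (n_points, n_points))).ravel()
    return zz, mm


def supmin_cut(zz, mm, delta: float):
    """[min, max] of the values attaining membership >= delta."""
    mask = mm >= delta - 1e-12
    return float(zz[mask].min()), float(zz[mask].max())
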