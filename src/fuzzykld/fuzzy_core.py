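"""Fuzzy numbers represented by finite families of δ-cuts.

A fuzzy number is described by its characterizing (membership) function
ξ: R → [0, 1].  For every level δ ∈ (0, 1] the δ-cut

    C_δ = {x : ξ(x) ≥ δ}

is a finite union of compact intervals, and the support {x : ξ(x) > 0} is
bounded.  A *fuzzy interval* is the special case where every δ-cut is a
single closed bounded interval.

This module stores fuzzy numbers on a finite ascending δ-grid (20 levels
0.05, 0.10, …, 1.00 by default).  All arithmetic is exact on the grid and
conservative between levels: querying a level that is not on the grid
returns the stored cut at the nearest grid level ≥ δ.

Interval arithmetic on δ-cuts implements the sup–min extension principle
for fuzzy intervals:

* sum:      C_δ(x ⊕ y) = [a_x + a_y, b_x + b_y]
* product:  C_δ(x ⊗ y) = [min, max] of x·y over C_δ(x) × C_δ(y)
* mean:     endpoint-wise arithmetic mean

Lower/upper expectations and the fuzzy correlation coefficient are
computed from a piecewise "sided" description of the membership function
(flat top [t_l1, t_r1], non-decreasing left side f, non-increasing right
side g).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "DEFAULT_DELTA_GRID",
    "FuzzyNumber",
    "FuzzyInterval",
    "SidedDescription",
    "delta_cut",
    "membership_from_cuts",
    "fuzzy_add",
    "fuzzy_multiply",
    "fuzzy_mean",
    "expectations",
    "fuzzy_correlation",
]

#: default 20-level grid {0.05, 0.10, ..., 1.00}
DEFAULT_DELTA_GRID = np.round(np.arange(1, 21) * 0.05, 10)

_TOL = 1e-9


def _as_intervals(cut) -> np.ndarray:
    """Coerce a cut to a (k, 2) float array of [a, b] intervals."""
    arr = np.atleast_2d(np.asarray(cut, dtype=float))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"a cut must be a list of [a, b] pairs, got shape {arr.shape}")
    return arr


def _union_contains(outer: np.ndarray, inner: np.ndarray, tol: float = _TOL) -> bool:
    """True if every interval of `inner` lies inside the union of `outer`."""
    for a, b in inner:
        covered = False
        for c, d in outer:
            if a >= c - tol and b <= d + tol:
                covered = True
                break
        if not covered:
            return False
    return True


class FuzzyNumber:
    """A fuzzy number stored as δ-cuts on a finite ascending level grid.

    Parameters
    ----------
    delta_grid:
        Ascending levels in (0, 1].
    cuts:
        One cut per level; each cut is a sequence of [a, b] intervals
        (a ≤ b).  Cuts must nest: the cut at a higher level is contained
        in the union of the cut at any lower level.
    support:
        Closed interval containing every cut.  Defaults to the hull of
        the lowest-level cut.
    """

    def __init__(self, delta_grid, cuts, support=None, validate: bool = True):
        grid = np.asarray(delta_grid, dtype=float)
        cuts = [_as_intervals(c) for c in cuts]
        if support is None:
            lo = min(float(c[:, 0].min()) for c in cuts)
            hi = max(float(c[:, 1].max()) for c in cuts)
            support = (lo, hi)
        self.delta_grid = grid
        self.cuts = cuts
        self.support = (float(support[0]), float(support[1]))
        if validate:
            self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        grid = self.delta_grid
        if grid.ndim != 1 or len(grid) == 0:
            raise ValueError("delta_grid must be a non-empty 1-D array")
        if np.any(grid <= 0) or np.any(grid > 1):
            raise ValueError("delta levels must lie in (0, 1]")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("delta_grid must be strictly ascending")
        if len(self.cuts) != len(grid):
            raise ValueError("need exactly one cut per level")
        lo, hi = self.support
        for cut in self.cuts:
            if not np.all(np.isfinite(cut)):
                raise ValueError("cut endpoints must be finite")
            if np.any(cut[:, 0] > cut[:, 1] + _TOL):
                raise ValueError("cut intervals must satisfy a <= b")
            if cut[:, 0].min() < lo - _TOL or cut[:, 1].max() > hi + _TOL:
                raise ValueError("cuts must lie inside the support")
        # nesting across every stored pair of levels
        for i in range(len(grid) - 1):
            if not _union_contains(self.cuts[i], self.cuts[i + 1]):
                raise ValueError(
                    f"cuts do not nest between levels {grid[i]} and {grid[i + 1]}"
                )

    # -- queries ---------------------------------------------------------
    def delta_cut(self, delta: float) -> np.ndarray:
        """Cut at level `delta`: the stored cut at the nearest grid level ≥ δ."""
        if not 0.0 < delta <= 1.0:
            raise ValueError(f"delta must lie in (0, 1], got {delta}")
        idx = int(np.searchsorted(self.delta_grid, delta - _TOL, side="left"))
        if idx >= len(self.delta_grid):
            idx = len(self.delta_grid) - 1
        return self.cuts[idx].copy()

    def membership(self, t: float) -> float:
        """Membership ξ(t) reconstructed from the stored cuts.

        ξ(t) = max{δ · 1_{C_δ}(t)} over the grid; 0 outside the support.
        """
        t = float(t)
        lo, hi = self.support
        if t < lo - _TOL or t > hi + _TOL:
            return 0.0
        best = 0.0
        for delta, cut in zip(self.delta_grid, self.cuts):
            inside = np.any((cut[:, 0] - _TOL <= t) & (t <= cut[:, 1] + _TOL))
            if inside:
                best = float(delta)
        return best

    @property
    def n_levels(self) -> int:
        return len(self.delta_grid)

    def is_interval(self) -> bool:
        return all(len(c) == 1 for c in self.cuts)

    def as_interval(self) -> "FuzzyInterval":
        if not self.is_interval():
            raise ValueError("fuzzy number has multi-interval cuts")
        return FuzzyInterval(self.delta_grid, self.cuts, self.support, validate=False)

    # -- construction helpers -------------------------------------------
    @classmethod
    def crisp(cls, c: float, delta_grid=None):
        grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid, float)
        cuts = [[[c, c]] for _ in grid]
        return cls(grid, cuts, support=(c, c), validate=False)

    @classmethod
    def from_membership(cls, func: Callable[[np.ndarray], np.ndarray],
                        support: tuple[float, float], delta_grid=None, n_points: int = 2001):
        """Build cuts by scanning `func` on a dense grid over `support`."""
        grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid, float)
        xs = np.linspace(support[0], support[1], n_points)
        vals = np.asarray(func(xs), dtype=float)
        if vals.min() < -_TOL or vals.max() > 1 + _TOL:
            raise ValueError("membership values must lie in [0, 1]")
        cuts = []
        for delta in grid:
            mask = vals >= delta - _TOL
            if not mask.any():
                # degenerate: peak below this level; use argmax point
                j = int(np.argmax(vals))
                cuts.append([[xs[j], xs[j]]])
                continue
            # contiguous runs of True -> intervals
            idx = np.flatnonzero(mask)
            splits = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate(([0], splits + 1))
            ends = np.concatenate((splits, [len(idx) - 1]))
            cuts.append([[xs[idx[s]], xs[idx[e]]] for s, e in zip(starts, ends)])
        return cls(grid, cuts, support=support)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "delta_grid": self.delta_grid.tolist(),
            "cuts": [c.tolist() for c in self.cuts],
            "support": list(self.support),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyNumber":
        return cls(d["delta_grid"], d["cuts"], d.get("support"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FuzzyNumber":
        return cls.from_dict(json.loads(s))

    def __eq__(self, other) -> bool:
        if not isinstance(other, FuzzyNumber):
            return NotImplemented
        return (
            np.array_equal(self.delta_grid, other.delta_grid)
            and len(self.cuts) == len(other.cuts)
            and all(np.array_equal(a, b) for a, b in zip(self.cuts, other.cuts))
            and self.support == other.support
        )

    def __repr__(self) -> str:
        lo, hi = self.support
        return (f"{type(self).__name__}(levels={self.n_levels}, "
                f"support=[{lo:.6g}, {hi:.6g}])")


class FuzzyInterval(FuzzyNumber):
    """Fuzzy number whose every δ-cut is a single closed bounded interval."""

    def _validate(self) -> None:
        super()._validate()
        for cut in self.cuts:
            if len(cut) != 1:
                raise ValueError("a fuzzy interval has exactly one interval per level")

    @property
    def lowers(self) -> np.ndarray:
        return np.array([c[0, 0] for c in self.cuts])

    @property
    def uppers(self) -> np.ndarray:
        return np.array([c[0, 1] for c in self.cuts])

    @classmethod
    def from_bounds(cls, delta_grid, lowers, uppers, support=None) -> "FuzzyInterval":
        cuts = [[[float(a), float(b)]] for a, b in zip(lowers, uppers)]
        return cls(delta_grid, cuts, support)

    @classmethod
    def triangular(cls, a: float, m: float, b: float, delta_grid=None) -> "FuzzyInterval":
        """Triangular membership with support [a, b] and peak at m."""
        grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid, float)
        lowers = a + grid * (m - a)
        uppers = b - grid * (b - m)
        return cls.from_bounds(grid, lowers, uppers, support=(a, b))

    @classmethod
    def trapezoidal(cls, a: float, m1: float, m2: float, b: float,
                    delta_grid=None) -> "FuzzyInterval":
        grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid, float)
        lowers = a + grid * (m1 - a)
        uppers = b - grid * (b - m2)
        return cls.from_bounds(grid, lowers, uppers, support=(a, b))

    @classmethod
    def crisp(cls, c: float, delta_grid=None) -> "FuzzyInterval":
        grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid, float)
        return cls.from_bounds(grid, np.full(len(grid), c), np.full(len(grid), c),
                               support=(c, c))

    def resample(self, delta_grid) -> "FuzzyInterval":
        """Resample onto another grid using the conservative outer-cut rule."""
        grid = np.asarray(delta_grid, dtype=float)
        cuts = [self.delta_cut(d)[:1] for d in grid]
        fi = FuzzyInterval(grid, cuts, self.support, validate=False)
        return fi


# --------------------------------------------------------------------------
# module-level operation front-ends


def delta_cut(x: FuzzyNumber, delta: float) -> np.ndarray:
    """δ-cut of `x` at level `delta` (nearest stored level ≥ δ)."""
    return x.delta_cut(delta)


def membership_from_cuts(x: FuzzyNumber, t: float) -> float:
    """Membership value ξ(t) reconstructed from stored δ-cuts."""
    return x.membership(t)


def _common_grid(xs: Sequence[FuzzyInterval]) -> np.ndarray:
    grids = [x.delta_grid for x in xs]
    if all(np.array_equal(grids[0], g) for g in grids[1:]):
        return grids[0]
    return np.unique(np.concatenate(grids))


def fuzzy_add(x1: FuzzyInterval, x2: FuzzyInterval) -> FuzzyInterval:
    """Fuzzy sum: per level [a1 + a2, b1 + b2]."""
    grid = _common_grid([x1, x2])
    a, b = x1.resample(grid), x2.resample(grid)
    lowers = a.lowers + b.lowers
    uppers = a.uppers + b.uppers
    support = (a.support[0] + b.support[0], a.support[1] + b.support[1])
    return FuzzyInterval.from_bounds(grid, lowers, uppers, support)


def fuzzy_multiply(x1: FuzzyInterval, x2: FuzzyInterval) -> FuzzyInterval:
    """Fuzzy product: per level the extrema of x·y over the cut box.

    For interval cuts the extrema are attained at the four endpoint
    products (the map is bilinear in (x, y)).
    """
    grid = _common_grid([x1, x2])
    a, b = x1.resample(grid), x2.resample(grid)
    prods = np.stack([
        a.lowers * b.lowers, a.lowers * b.uppers,
        a.uppers * b.lowers, a.uppers * b.uppers,
    ])
    lowers, uppers = prods.min(axis=0), prods.max(axis=0)
    sp = [a.support[0] * b.support[0], a.support[0] * b.support[1],
          a.support[1] * b.support[0], a.support[1] * b.support[1]]
    return FuzzyInterval.from_bounds(grid, lowers, uppers, (min(sp), max(sp)))


def fuzzy_mean(xs: Sequence[FuzzyInterval]) -> FuzzyInterval:
    """Fuzzy arithmetic mean: endpoint-wise means per level."""
    xs = list(xs)
    if len(xs) == 0:
        raise ValueError("fuzzy_mean requires at least one fuzzy interval")
    grid = _common_grid(xs)
    rs = [x.resample(grid) for x in xs]
    lowers = np.mean([r.lowers for r in rs], axis=0)
    uppers = np.mean([r.uppers for r in rs], axis=0)
    support = (float(np.mean([r.support[0] for r in rs])),
               float(np.mean([r.support[1] for r in rs])))
    return FuzzyInterval.from_bounds(grid, lowers, uppers, support)


# --------------------------------------------------------------------------
# sided description, expectations, correlation


@dataclass
class SidedDescription:
    """Piecewise description of a membership function.

    ξ(t) = 0 left of t_l0, rises through f on [t_l0, t_l1), equals 1 on
    [t_l1, t_r1], falls through g on (t_r1, t_r0], and is 0 to the right.
    """

    t_l0: float
    t_l1: float
    t_r1: float
    t_r0: float
    f: Callable[[float], float] | None = None
    g: Callable[[float], float] | None = None

    def __post_init__(self):
        if not (self.t_l0 <= self.t_l1 <= self.t_r1 <= self.t_r0):
            raise ValueError("knots must satisfy t_l0 <= t_l1 <= t_r1 <= t_r0")

    @classmethod
    def crisp(cls, c: float) -> "SidedDescription":
        return cls(c, c, c, c)

    @classmethod
    def triangular(cls, a: float, m: float, b: float) -> "SidedDescription":
        f = (lambda t: (t - a) / (m - a)) if m > a else None
        g = (lambda t: (b - t) / (b - m)) if b > m else None
        return cls(a, m, m, b, f, g)


def expectations(x: SidedDescription) -> tuple[float, float]:
    """Lower and upper expected values of a fuzzy number.

    lower = t_l1 − ∫_{t_l0}^{t_l1} f,  upper = t_r1 + ∫_{t_r1}^{t_r0} g.
    """
    lower = float(x.t_l1)
    if x.t_l1 > x.t_l0:
        if x.f is None:
            raise ValueError("left side f required when t_l0 < t_l1")
        val, _ = integrate.quad(x.f, x.t_l0, x.t_l1, limit=200)
        if not np.isfinite(val):
            raise FloatingPointError("non-finite left-side integral")
        lower -= val
    upper = float(x.t_r1)
    if x.t_r0 > x.t_r1:
        if x.g is None:
            raise ValueError("right side g required when t_r1 < t_r0")
        val, _ = integrate.quad(x.g, x.t_r1, x.t_r0, limit=200)
        if not np.isfinite(val):
            raise FloatingPointError("non-finite right-side integral")
        upper += val
    if lower > upper + 1e-9:
        raise FloatingPointError("lower expectation exceeds upper expectation")
    return lower, upper


def fuzzy_correlation(x: SidedDescription, y: SidedDescription) -> tuple[float, float]:
    """Correlation C(x, y) and correlation coefficient ρ(x, y).

    C(x, y) = E_l(x) E_l(y) + E_u(x) E_u(y);
    ρ(x, y) = C(x, y) / sqrt(C(x, x) C(y, y)).
    """
    elx, eux = expectations(x)
    ely, euy = expectations(y)
    c_xy = elx * ely + eux * euy
    c_xx = elx * elx + eux * eux
    c_yy = ely * ely + euy * euy
    if c_xx <= 0 or c_yy <= 0:
        raise ZeroDivisionError("undefined correlation coefficient: "
                                "zero self-correlation")
    rho = c_xy / np.sqrt(c_xx * c_yy)
    return float(c_xy), float(rho)
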