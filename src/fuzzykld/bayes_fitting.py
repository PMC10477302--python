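"""Family selection, grid posteriors, and parameter fuzzification.

The pipeline implemented here turns a crisp sample into a distribution
whose parameters are fuzzy numbers:

1. *Family selection*: each candidate family whose support admits the
   sample is fitted by the method of moments, the extended KL divergence
   of the fitted model from the sample's empirical partition is computed,
   and the family with the smallest divergence wins.

2. *Grid posterior*: the posterior density of the winning family's
   parameters, prior × likelihood normalized to integrate to 1, is
   evaluated on a regular grid spanning the moment estimate ± 6 rough
   standard errors per parameter (flat prior by default).

3. *Mode adjustment and fuzzification*: each parameter's marginal
   posterior f(θ) is rescaled by its mode value, f̃(θ) = f(θ)/f(θ_Mode),
   so the maximum is exactly 1; the superlevel sets {θ: f̃(θ) ≥ δ} then
   serve as δ-cuts of a fuzzy number.  Disconnected level sets (possible
   for multimodal posteriors) are collapsed to their convex hull, since
   a single-family posterior is expected to be unimodal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .divergence import (
    EmpiricalPartition,
    FuzzyParametricDistribution,
    build_partition,
    extended_kld,
)
from .fuzzy_core import DEFAULT_DELTA_GRID, FuzzyInterval
from .parametric import (
    FAMILIES,
    FamilyError,
    ParametricDistribution,
    family_applicable,
    loglik_grid,
    moment_fit,
    param_bounds,
    suff_stats,
)

__all__ = [
    "DEFAULT_CANDIDATES",
    "ParameterGrid",
    "AdjustedDensity",
    "select_family",
    "grid_posterior",
    "adjust_to_mode",
    "fuzzify_parameter",
    "fit_fuzzy_distribution",
]

DEFAULT_CANDIDATES = ("normal", "gamma", "exponential", "uniform", "lognormal")


@dataclass
class ParameterGrid:
    """Joint posterior density on a regular parameter grid.

    ``axes`` maps parameter names to ascending 1-D grids; ``density`` has
    one axis per parameter (meshgrid 'ij' order) and integrates to 1 by
    the trapezoid rule.  Parameters held fixed are in ``fixed``.
    """

    family: str
    param_names: tuple[str, ...]
    axes: dict
    density: np.ndarray
    fixed: dict

    def __post_init__(self):
        shape = tuple(len(self.axes[p]) for p in self.param_names)
        if self.density.shape != shape:
            raise ValueError("density shape does not match the axes")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        z = self.density
        for p in reversed(self.param_names):
            z = np.trapezoid(z, self.axes[p], axis=-1)
        return float(z)

    def marginal(self, parameter: str) -> tuple[np.ndarray, np.ndarray]:
        """(grid, marginal density) of one parameter."""
        if parameter not in self.param_names:
            raise KeyError(f"{parameter!r} is not a free parameter")
        z = self.density
        names = list(self.param_names)
        while len(names) > 1:
            for p in list(names):
                if p != parameter:
                    ax = names.index(p)
                    z = np.trapezoid(z, self.axes[p], axis=ax)
                    names.remove(p)
                    break
        return np.asarray(self.axes[parameter]), z


@dataclass
class AdjustedDensity:
    """A marginal posterior rescaled by its mode value: max = 1 at θ_Mode."""

    parameter: str
    grid: np.ndarray
    values: np.ndarray
    mode: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.max() != 1.0:
            raise ValueError("adjusted density must have maximum exactly 1")
        if np.any(self.values < 0) or np.any(self.values > 1.0 + 1e-12):
            raise ValueError("adjusted density values must lie in [0, 1]")


def select_family(sample, candidates=DEFAULT_CANDIDATES, epsilon=None,
                  normalize_partition_mass: bool = False):
    """Pick the candidate family with the smallest extended KL divergence.

    Each applicable family (sample inside its support) is fitted by
    moments and scored against the sample's empirical partition.  Ties
    break by candidate order.  Returns (best ParametricDistribution,
    audit table with one row per applicable family).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 8:
        raise ValueError("select_family needs n >= 8")
    part = build_partition(x, epsilon)
    rows = []
    violations = []
    for fam in candidates:
        if not family_applicable(fam, x):
            violations.append(fam)
            continue
        try:
            dist = moment_fit(x, fam)
        except FamilyError as exc:
            violations.append(f"{fam} ({exc})")
            continue
        div = extended_kld(dist, part, normalize_partition_mass)
        rows.append({"family": fam, "divergence": div,
                     "params": dict(dist.params)})
    if not rows:
        raise FamilyError(
            f"no applicable candidate family; support violations: {violations}")
    table = pd.DataFrame(rows)
    best_row = table.loc[table["divergence"].idxmin()]
    best = ParametricDistribution(best_row["family"], best_row["params"])
    return best, table


# --------------------------------------------------------------------------
# grid posterior


def _rough_se(family: str, est: dict, sample: np.ndarray) -> dict:
    """Crude standard errors used only to size the posterior grid span."""
    n = len(sample)
    rn = np.sqrt(n)
    if family == "normal":
        return {"mean": est["sd"] / rn, "sd": est["sd"] / np.sqrt(2 * n)}
    if family == "gamma":
        return {"shape": est["shape"] * np.sqrt(10.0 / n) + 1e-12,
                "scale": est["scale"] * np.sqrt(10.0 / n) + 1e-12}
    if family == "exponential":
        return {"rate": est["rate"] / rn}
    if family == "uniform":
        width = est["upper"] - est["lower"]
        return {"lower": 3.0 * width / n + 1e-12,
                "upper": 3.0 * width / n + 1e-12}
    if family == "lognormal":
        return {"meanlog": est["sdlog"] / rn,
                "sdlog": est["sdlog"] / np.sqrt(2 * n)}
    raise FamilyError(f"unknown family {family!r}")


def grid_posterior(sample, family: str, prior="flat", grid_res: int = 201,
                   span: float = 6.0, fixed: dict | None = None) -> ParameterGrid:
    """Posterior density of the family parameters on a regular grid.

    weight(θ) ∝ prior(θ) · Π_i g(x_i|θ), computed in log-space from
    sufficient statistics and normalized so its trapezoid integral is 1.
    ``prior`` is "flat" or a ParameterGrid (whose axes and density are
    reused).  Parameters in ``fixed`` are pinned to crisp values.
    """
    x = np.asarray(sample, dtype=float)
    if family not in FAMILIES:
        raise FamilyError(f"unknown family {family!r}")
    if not family_applicable(family, x):
        raise FamilyError(f"{family}: sample violates the family support")
    fixed = dict(fixed or {})
    all_names = FAMILIES[family].param_names
    free_names = tuple(p for p in all_names if p not in fixed)
    if not free_names:
        raise ValueError("at least one parameter must remain free")

    if isinstance(prior, ParameterGrid):
        axes = {p: np.asarray(prior.axes[p], dtype=float) for p in free_names}
        log_prior = np.log(np.maximum(prior.density, 1e-300))
    else:
        if prior != "flat":
            raise ValueError("prior must be 'flat' or a ParameterGrid")
        est = moment_fit(x, family).params
        ses = _rough_se(family, est, x)
        bounds = param_bounds(family)
        axes = {}
        for p in free_names:
            lo = est[p] - span * ses[p]
            hi = est[p] + span * ses[p]
            blo, bhi = bounds[p]
            if blo is not None:
                lo = max(lo, blo + 1e-9 + (est[p] - blo) * 1e-6)
            if bhi is not None:
                hi = min(hi, bhi - 1e-9)
            if family == "uniform":
                # lower must stay <= min(x), upper >= max(x)
                if p == "lower":
                    hi = min(hi, float(x.min()))
                if p == "upper":
                    lo = max(lo, float(x.max()))
            if hi <= lo:
                hi = lo + abs(lo) * 1e-6 + 1e-9
            axes[p] = np.linspace(lo, hi, grid_res)
        log_prior = 0.0

    mesh_arrays = np.meshgrid(*[axes[p] for p in free_names], indexing="ij")
    mesh = {p: m for p, m in zip(free_names, mesh_arrays)}
    for p, v in fixed.items():
        mesh[p] = np.asarray(float(v))
    stats_ = suff_stats(family, x)
    with np.errstate(over="ignore"):
        logw = loglik_grid(family, mesh, stats_) + log_prior
    m = np.max(logw)
    if not np.isfinite(m):
        raise FloatingPointError(
            "likelihood vanished everywhere on the grid; widen the span")
    dens = np.exp(logw - m)
    pg = ParameterGrid(family, free_names, axes, dens, fixed)
    total = pg.integral()
    if total <= 0:
        raise FloatingPointError("posterior integral is zero; widen the span")
    pg.density = dens / total
    return pg


def adjust_to_mode(post: ParameterGrid, parameter: str) -> AdjustedDensity:
    """Marginal posterior of one parameter divided by its value at the mode."""
    grid, marg = post.marginal(parameter)
    peak = float(marg.max())
    if peak <= 0:
        raise FloatingPointError("marginal posterior is identically zero")
    imax = np.flatnonzero(marg == marg.max())
    if len(imax) > 1 and not np.all(np.diff(imax) == 1):
        warnings.warn(f"non-unique mode for {parameter}; using smallest",
                      RuntimeWarning, stacklevel=2)
    mode = float(grid[imax[0]])
    values = marg / peak
    values[imax[0]] = 1.0  # exact at the mode despite round-off
    return AdjustedDensity(parameter, grid, values, mode)


def fuzzify_parameter(ad: AdjustedDensity, delta_grid=None) -> FuzzyInterval:
    """Fuzzy number whose δ-cuts are the superlevel sets {θ: f̃(θ) ≥ δ}.

    Each level set is reported as the single interval from its smallest
    to its largest grid point (convex hull for disconnected sets, with a
    warning); the δ=1 cut is the mode point.
    """
    grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid, float)
    lowers, uppers = [], []
    for delta in grid:
        idx = np.flatnonzero(ad.values >= delta - 1e-12)
        if len(idx) == 0:
            idx = np.array([int(np.argmax(ad.values))])
        if np.any(np.diff(idx) > 1):
            warnings.warn(
                f"disconnected level set at delta={delta:.3g} for "
                f"{ad.parameter}; taking the convex hull",
                RuntimeWarning, stacklevel=2)
        lowers.append(float(ad.grid[idx[0]]))
        uppers.append(float(ad.grid[idx[-1]]))
    return FuzzyInterval.from_bounds(
        grid, lowers, uppers, support=(min(lowers), max(uppers)))


def fit_fuzzy_distribution(sample, candidates=DEFAULT_CANDIDATES,
                           prior="flat", delta_grid=None, grid_res: int = 201,
                           epsilon=None) -> FuzzyParametricDistribution:
    """Full pipeline: family selection → grid posterior → fuzzification.

    Returns a distribution whose every parameter is a fuzzy number; the
    δ=1 cuts sit at the marginal posterior modes.
    """
    best, _table = select_family(sample, candidates, epsilon)
    post = grid_posterior(sample, best.family, prior=prior, grid_res=grid_res)
    fuzzy_params = {}
    for p in post.param_names:
        ad = adjust_to_mode(post, p)
        fuzzy_params[p] = fuzzify_parameter(ad, delta_grid)
    for p, v in post.fixed.items():
        fuzzy_params[p] = FuzzyInterval.crisp(float(v), delta_grid)
    return FuzzyParametricDistribution(best.family, fuzzy_params)
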