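"""Classical, extended, and fuzzy extended Kullback–Leibler divergences.

Three divergences live here:

* ``kld_continuous`` — the classical D(f‖g) = ∫ f log(f/g) dx between two
  crisp parametric densities, by adaptive quadrature.

* ``extended_kld`` — a discretized divergence between a parametric model
  and the empirical distribution of a sample: the sorted sample induces
  consecutive half-open intervals (x_{t−1}, x_t], the left end extended
  by a margin ε below the minimum, and

      KLD(f‖emp) = Σ_t P_f(t) · log(P_f(t) / P_emp(t)).

  Because the model's mass outside [x_0, x_T] is ignored, the sum can be
  negative; an optional ``normalize_partition_mass`` switch renormalizes
  both probability vectors over the partition, which restores strict
  non-negativity.

* ``fuzzy_extended_kld`` — when the distribution parameters are fuzzy
  numbers, the divergence becomes a fuzzy number itself: its δ-cut is the
  [min, max] of the (extended or continuous) divergence as the parameters
  range over the Cartesian box of their δ-cuts.  The extrema are located
  by a dense grid over the widest box, per-level subsetting augmented
  with the level box's corners, and optional Nelder–Mead refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import integrate, optimize

from .fuzzy_core import DEFAULT_DELTA_GRID, FuzzyInterval, FuzzyNumber
from .parametric import (
    FAMILIES,
    ParametricDistribution,
    batch_cdf,
    param_bounds,
)

__all__ = [
    "EmpiricalPartition",
    "FuzzyParametricDistribution",
    "FuzzyDivergence",
    "build_partition",
    "kld_continuous",
    "extended_kld",
    "fuzzy_extended_kld",
]

#: floor applied to empirical interval probabilities inside the log
PROB_FLOOR = 1e-12


class SupportMismatchError(FloatingPointError):
    """g vanishes on a region where f has mass: the divergence is infinite."""


# --------------------------------------------------------------------------
# empirical partition


@dataclass(frozen=True)
class EmpiricalPartition:
    """Consecutive half-open intervals induced by a sorted sample.

    breakpoints x_0 < x_1 < … < x_T with x_0 = min(sample) − ε and
    x_T = max(sample); interval t is (x_{t−1}, x_t] and carries
    count_t observations.
    """

    breakpoints: np.ndarray
    counts: np.ndarray
    epsilon: float

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        ct = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "counts", ct)
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly ascending")
        if len(ct) != len(bp) - 1:
            raise ValueError("need one count per interval")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def build_partition(sample, epsilon: float | None = None) -> EmpiricalPartition:
    """Build the empirical partition of a sample.

    Ties are merged into a single breakpoint with summed count.  The
    default left-extension margin ε is one sample standard deviation
    divided by 100 (or 1e-6 for zero-variance guard).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("build_partition needs a 1-D sample with n >= 2")
    if epsilon is None:
        sd = float(np.std(x, ddof=1))
        epsilon = sd / 100.0 if sd > 0 else 1e-6
    values, counts = np.unique(x, return_counts=True)
    breakpoints = np.concatenate(([values[0] - epsilon], values))
    return EmpiricalPartition(breakpoints, counts, float(epsilon))


# --------------------------------------------------------------------------
# crisp divergences


def kld_continuous(f: ParametricDistribution, g: ParametricDistribution) -> float:
    """D(f‖g) = ∫ f log(f/g) by adaptive quadrature over the support of f.

    Raises SupportMismatchError when g is (numerically) zero on a set
    where f carries mass, in which case the divergence diverges.
    """
    flo, fhi = f.support()
    glo, ghi = g.support()
    # mass of f outside the support of g -> infinite divergence
    outside = f.cdf(max(glo, flo)) - f.cdf(flo) if glo > flo else 0.0
    outside += 1.0 - f.cdf(min(ghi, fhi)) if ghi < fhi else 0.0
    if outside > 1e-12:
        raise SupportMismatchError(
            "g has no support where f carries mass; divergence is infinite")

    fd, gd = f.dist, g.dist
    lo = max(flo, glo)
    hi = min(fhi, ghi)
    # clip an unbounded integration range to where f has essentially all mass
    if not np.isfinite(lo):
        lo = float(fd.ppf(1e-12))
    if not np.isfinite(hi):
        hi = float(fd.ppf(1 - 1e-12))

    def integrand(x):
        logf = fd.logpdf(x)
        if logf == -np.inf:
            return 0.0
        logg = gd.logpdf(x)
        if logg == -np.inf:
            return np.inf
        return np.exp(logf) * (logf - logg)

    val, _ = integrate.quad(integrand, lo, hi, limit=400)
    if not np.isfinite(val):
        raise SupportMismatchError("divergence integral is not finite")
    return max(float(val), 0.0) if abs(val) < 1e-9 else float(val)


def _extended_kld_from_probs(p_f: np.ndarray, p_emp: np.ndarray,
                             normalize: bool,
                             direction: str = "model") -> np.ndarray:
    """Row-wise divergence between model and empirical interval probabilities.

    ``direction="model"``: Σ p_f log(p_f / p_emp) — the definitional form,
    with the model in the weighting slot.  ``direction="empirical"``:
    Σ p_emp log(p_emp / p_f) — the empirical distribution weighted, which
    ranks models by their multinomial log-likelihood of the data.  Both
    use the 0·log 0 = 0 convention and floor the denominator at 1e-12.
    """
    pf = np.atleast_2d(p_f)
    pe = np.broadcast_to(p_emp, pf.shape)
    if normalize:
        tot = pf.sum(axis=1, keepdims=True)
        pf = np.divide(pf, tot, out=np.zeros_like(pf), where=tot > 0)
        pe = pe / pe.sum(axis=1, keepdims=True)
    if direction == "model":
        w, ref = pf, np.maximum(pe, PROB_FLOOR)
    elif direction == "empirical":
        w, ref = pe, np.maximum(pf, PROB_FLOOR)
    else:
        raise ValueError("direction must be 'model' or 'empirical'")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = w * np.log(w / ref)
    terms = np.where(w > 0, terms, 0.0)
    out = terms.sum(axis=1)
    if normalize and direction == "model":
        out = np.maximum(out, 0.0)
    return out


def extended_kld(f: ParametricDistribution, part: EmpiricalPartition,
                 normalize_partition_mass: bool = False,
                 direction: str = "model") -> float:
    """Discretized divergence of model `f` from the empirical partition.

    Model interval probabilities are cdf increments over the partition's
    breakpoints; empirical ones are count fractions (floored at 1e-12
    inside the log).  With ``normalize_partition_mass`` both vectors are
    renormalized over the partition, making the model-weighted result
    non-negative.  ``direction`` chooses the weighting slot (see
    ``_extended_kld_from_probs``); the model-weighted form is the default.
    """
    cdf_vals = f.cdf(part.breakpoints)
    p_f = np.clip(np.diff(cdf_vals), 0.0, 1.0)
    return float(_extended_kld_from_probs(p_f, part.probabilities,
                                          normalize_partition_mass,
                                          direction)[0])


# --------------------------------------------------------------------------
# fuzzy parametric distributions and the fuzzy divergence


@dataclass(frozen=True)
class FuzzyParametricDistribution:
    """A distribution family with one fuzzy number per parameter."""

    family: str
    params: dict  # name -> FuzzyNumber (crisp floats are promoted)

    def __post_init__(self):
        fam = FAMILIES.get(self.family)
        if fam is None:
            raise ValueError(f"unknown family {self.family!r}")
        promoted = {}
        for name in fam.param_names:
            if name not in self.params:
                raise ValueError(f"{self.family}: missing parameter {name!r}")
            v = self.params[name]
            if not isinstance(v, FuzzyNumber):
                v = FuzzyInterval.crisp(float(v))
            promoted[name] = v
        object.__setattr__(self, "params", promoted)
        bounds = param_bounds(self.family)
        for name, fz in self.params.items():
            (a, b), = fz.delta_cut(1.0)[:1]
            lo, hi = bounds[name]
            if (lo is not None and a <= lo) or (hi is not None and b >= hi):
                raise ValueError(
                    f"{self.family}: δ=1 cut of {name} outside the domain")

    @property
    def param_names(self) -> tuple[str, ...]:
        return FAMILIES[self.family].param_names

    def crisp(self) -> ParametricDistribution:
        """Point distribution at the δ=1 cut midpoints (the modes)."""
        vals = {}
        for name in self.param_names:
            (a, b), = self.params[name].delta_cut(1.0)[:1]
            vals[name] = 0.5 * (a + b)
        return ParametricDistribution(self.family, vals)

    def delta_grid(self) -> np.ndarray:
        grids = [fz.delta_grid for fz in self.params.values()]
        if all(np.array_equal(grids[0], g) for g in grids[1:]):
            return grids[0]
        return np.unique(np.concatenate(grids))

    def param_box(self, delta: float) -> list[tuple[float, float]]:
        """Per-parameter [lo, hi] at level δ (hull of the δ-cut)."""
        box = []
        for name in self.param_names:
            cut = self.params[name].delta_cut(delta)
            box.append((float(cut[:, 0].min()), float(cut[:, 1].max())))
        return box

    def to_dict(self) -> dict:
        return {"family": self.family,
                "params": {k: v.to_dict() for k, v in self.params.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyParametricDistribution":
        params = {k: FuzzyNumber.from_dict(v) for k, v in d["params"].items()}
        params = {k: (v.as_interval() if v.is_interval() else v)
                  for k, v in params.items()}
        return cls(d["family"], params)


class FuzzyDivergence(FuzzyInterval):
    """A fuzzy interval over divergence values, with per-level [min, max] cuts."""

    def defuzzify(self, method: str = "midpoint") -> float:
        """Collapse to a single ranking score.

        ``midpoint``: mean of δ-cut midpoints (centroid-like; reduces to
        the crisp value for degenerate cuts).  ``pessimistic``: mean of
        the upper endpoints.
        """
        if method == "midpoint":
            return float(np.mean(0.5 * (self.lowers + self.uppers)))
        if method == "pessimistic":
            return float(np.mean(self.uppers))
        raise ValueError(f"unknown defuzzification method {method!r}")


def _free_parameters(dists):
    """(dist_index, name, fuzzy_number) for every non-crisp parameter."""
    free = []
    for di, d in enumerate(dists):
        if d is None:
            continue
        for name in d.param_names:
            fz = d.params[name]
            w = fz.support[1] - fz.support[0]
            if w > 0:
                free.append((di, name, fz))
    return free


def fuzzy_extended_kld(
    f: FuzzyParametricDistribution | ParametricDistribution,
    g: Union["FuzzyParametricDistribution", ParametricDistribution,
             EmpiricalPartition],
    grid_res: int = 21,
    delta_grid=None,
    mode: str | None = None,
    refine: bool = True,
    normalize_partition_mass: bool = False,
    direction: str = "model",
) -> FuzzyDivergence:
    """Fuzzy extended KL divergence KLD*(f‖g).

    Per δ level the cut is the [min, max] of the divergence over the
    Cartesian box of the parameters' δ-cuts.  When ``g`` is an
    EmpiricalPartition the discretized (extended) divergence is used;
    between two parametric distributions the continuous divergence is
    the default.

    The extrema are located on a dense grid (``grid_res`` points per free
    parameter) laid over the widest box, restricted per level and
    augmented with the level box's corners and centre; with
    ``refine=True`` a bounded Nelder–Mead polish runs from the best grid
    point of each level.  Cuts are forced to nest by an outer-envelope
    pass from δ=1 downwards.
    """
    if grid_res < 2:
        raise ValueError("grid_res must be >= 2")

    if isinstance(f, ParametricDistribution):
        f = FuzzyParametricDistribution(f.family, dict(f.params))
    g_is_partition = isinstance(g, EmpiricalPartition)
    if not g_is_partition and isinstance(g, ParametricDistribution):
        g = FuzzyParametricDistribution(g.family, dict(g.params))

    if mode is None:
        mode = "extended" if g_is_partition else "continuous"
    if mode == "extended" and not g_is_partition:
        raise ValueError("extended mode requires an EmpiricalPartition for g")

    dists = [f, None if g_is_partition else g]
    free = _free_parameters(dists)
    ndim = len(free)

    if delta_grid is None:
        grids = [fz.delta_grid for _, _, fz in free]
        if grids:
            delta_grid = grids[0] if all(
                np.array_equal(grids[0], gr) for gr in grids[1:]
            ) else np.unique(np.concatenate(grids))
        else:
            delta_grid = DEFAULT_DELTA_GRID
    delta_grid = np.asarray(delta_grid, dtype=float)

    # ---- objective -------------------------------------------------------
    fam_f = f.family
    nf = len(f.param_names)
    if g_is_partition:
        p_emp = g.probabilities
        bps = g.breakpoints

        def evaluate(thetas: np.ndarray) -> np.ndarray:
            # thetas: (m, ndim) free parameters; fill crisp values
            m = thetas.shape[0]
            full = np.empty((m, nf))
            for j, name in enumerate(f.param_names):
                fz = f.params[name]
                w = fz.support[1] - fz.support[0]
                if w > 0:
                    k = next(i for i, (di, nm, _) in enumerate(free)
                             if di == 0 and nm == name)
                    full[:, j] = thetas[:, k]
                else:
                    full[:, j] = fz.support[0]
            cdf = batch_cdf(fam_f, full, bps)
            p_f = np.clip(np.diff(cdf, axis=1), 0.0, 1.0)
            return _extended_kld_from_probs(p_f, p_emp,
                                            normalize_partition_mass,
                                            direction)
    else:
        def evaluate(thetas: np.ndarray) -> np.ndarray:
            out = np.empty(thetas.shape[0])
            for i, th in enumerate(thetas):
                vals_f, vals_g = {}, {}
                k = 0
                for di, d, store in ((0, f, vals_f), (1, g, vals_g)):
                    for name in d.param_names:
                        fz = d.params[name]
                        w = fz.support[1] - fz.support[0]
                        if w > 0:
                            store[name] = float(th[
                                next(ii for ii, (dj, nm, _) in enumerate(free)
                                     if dj == di and nm == name)])
                        else:
                            store[name] = fz.support[0]
                df = ParametricDistribution(f.family, vals_f)
                dg = ParametricDistribution(g.family, vals_g)
                out[i] = kld_continuous(df, dg)
            return out

    # ---- degenerate (all crisp) case ------------------------------------
    if ndim == 0:
        v = float(evaluate(np.zeros((1, 0)))[0])
        n = len(delta_grid)
        return FuzzyDivergence.from_bounds(delta_grid, np.full(n, v),
                                           np.full(n, v), support=(v, v))

    # ---- shared dense grid over the widest box ---------------------------
    delta_min = float(delta_grid.min())
    boxes_wide = []
    for di, name, fz in free:
        d = dists[di]
        lo, hi = d.param_box(delta_min)[d.param_names.index(name)]
        boxes_wide.append((lo, hi))
    axes = [np.linspace(lo, hi, grid_res) for lo, hi in boxes_wide]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    vals = evaluate(pts)

    # ---- per-level extrema, descending δ, with nesting envelope ----------
    order = np.argsort(delta_grid)[::-1]
    lowers = np.empty(len(delta_grid))
    uppers = np.empty(len(delta_grid))
    run_lo, run_hi = np.inf, -np.inf
    for idx in order:
        delta = float(delta_grid[idx])
        level_box = []
        for di, name, _ in free:
            d = dists[di]
            level_box.append(d.param_box(delta)[d.param_names.index(name)])
        mask = np.ones(len(pts), dtype=bool)
        for k, (lo, hi) in enumerate(level_box):
            mask &= (pts[:, k] >= lo - 1e-12) & (pts[:, k] <= hi + 1e-12)
        # corners + centre of the level box, always evaluated
        corners = np.array(np.meshgrid(*[[lo, hi] for lo, hi in level_box],
                                       indexing="ij")).reshape(ndim, -1).T
        centre = np.array([[0.5 * (lo + hi) for lo, hi in level_box]])
        extra_pts = np.vstack([corners, centre])
        extra_vals = evaluate(extra_pts)
        cand_vals = np.concatenate([vals[mask], extra_vals])
        cand_pts = np.vstack([pts[mask], extra_pts])
        vmin = float(cand_vals.min())
        vmax = float(cand_vals.max())
        degenerate = all(hi - lo <= 0 for lo, hi in level_box)
        if refine and not degenerate:
            lob = np.array([b[0] for b in level_box])
            upb = np.array([b[1] for b in level_box])

            def _scalar(th, sign):
                th = np.clip(th, lob, upb)
                return sign * float(evaluate(th[None, :])[0])

            for sign, start, best in ((1.0, cand_pts[np.argmin(cand_vals)], vmin),
                                      (-1.0, cand_pts[np.argmax(cand_vals)], -vmax)):
                res = optimize.minimize(
                    _scalar, start, args=(sign,), method="Nelder-Mead",
                    options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 80})
                if res.fun < best:
                    if sign > 0:
                        vmin = float(res.fun)
                    else:
                        vmax = float(-res.fun)
        run_lo = min(run_lo, vmin)
        run_hi = max(run_hi, vmax)
        lowers[idx] = run_lo
        uppers[idx] = run_hi

    if normalize_partition_mass or mode == "continuous":
        lowers = np.maximum(lowers, 0.0)
        uppers = np.maximum(uppers, lowers)
    return FuzzyDivergence.from_bounds(delta_grid, lowers, uppers,
                                       support=(float(lowers.min()),
                                                float(uppers.max())))
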