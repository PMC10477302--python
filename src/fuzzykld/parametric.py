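"""Crisp parametric distribution families and moment-based estimation.

Five families are supported: normal(mean, sd), gamma(shape k, scale θ)
with mean kθ and variance kθ², exponential(rate λ), uniform(lower,
upper), and lognormal(meanlog, sdlog).  scipy.stats supplies pdf/cdf/
sampling; estimation is method-of-moments (the sample mean and standard
deviation stand in for the distribution's mean and standard deviation),
which is the estimator the family-selection algorithm prescribes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "ParametricDistribution",
    "make_distribution",
    "moment_fit",
    "interval_probability",
    "param_bounds",
]


class FamilyError(ValueError):
    """Raised when parameters violate a family's domain or a sample its support."""


@dataclass(frozen=True)
class _Family:
    name: str
    param_names: tuple[str, ...]
    # open/closed domain bounds per parameter, (low, high); None = unbounded
    bounds: tuple[tuple[float | None, float | None], ...]
    frozen: Callable[..., "stats.rv_continuous"]
    fit: Callable[[np.ndarray], dict]
    supports: Callable[[np.ndarray], bool]


def _check_domain(fam: "_Family", params: dict) -> None:
    missing = set(fam.param_names) - set(params)
    if missing:
        raise FamilyError(f"{fam.name}: missing parameters {sorted(missing)}")
    for name, (lo, hi) in zip(fam.param_names, fam.bounds):
        v = params[name]
        if not np.isfinite(v):
            raise FamilyError(f"{fam.name}: parameter {name}={v} must be finite")
        if lo is not None and v <= lo:
            raise FamilyError(f"{fam.name}: parameter {name}={v} must be > {lo}")
        if hi is not None and v >= hi:
            raise FamilyError(f"{fam.name}: parameter {name}={v} must be < {hi}")
    if fam.name == "uniform" and params["lower"] >= params["upper"]:
        raise FamilyError("uniform: requires lower < upper")


def _fit_normal(x):
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}


def _fit_gamma(x):
    m, v = float(np.mean(x)), float(np.var(x, ddof=1))
    if v <= 0:
        raise FamilyError("gamma: degenerate sample (zero variance)")
    return {"shape": m * m / v, "scale": v / m}


def _fit_exponential(x):
    m = float(np.mean(x))
    if m <= 0:
        raise FamilyError("exponential: non-positive sample mean")
    return {"rate": 1.0 / m}


def _fit_uniform(x):
    return {"lower": float(np.min(x)), "upper": float(np.max(x))}


def _fit_lognormal(x):
    lx = np.log(x)
    return {"meanlog": float(np.mean(lx)), "sdlog": float(np.std(lx, ddof=1))}


FAMILIES: dict[str, _Family] = {
    "normal": _Family(
        "normal", ("mean", "sd"), ((None, None), (0.0, None)),
        lambda mean, sd: stats.norm(loc=mean, scale=sd),
        _fit_normal, lambda x: True,
    ),
    "gamma": _Family(
        "gamma", ("shape", "scale"), ((0.0, None), (0.0, None)),
        lambda shape, scale: stats.gamma(a=shape, scale=scale),
        _fit_gamma, lambda x: bool(np.all(x > 0)),
    ),
    "exponential": _Family(
        "exponential", ("rate",), ((0.0, None),),
        lambda rate: stats.expon(scale=1.0 / rate),
        _fit_exponential, lambda x: bool(np.all(x >= 0)),
    ),
    "uniform": _Family(
        "uniform", ("lower", "upper"), ((None, None), (None, None)),
        lambda lower, upper: stats.uniform(loc=lower, scale=upper - lower),
        _fit_uniform, lambda x: True,
    ),
    "lognormal": _Family(
        "lognormal", ("meanlog", "sdlog"), ((None, None), (0.0, None)),
        lambda meanlog, sdlog: stats.lognorm(s=sdlog, scale=np.exp(meanlog)),
        _fit_lognormal, lambda x: bool(np.all(x > 0)),
    ),
}


@dataclass(frozen=True)
class ParametricDistribution:
    """A named distribution family with a crisp parameter vector."""

    family: str
    params: dict

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise FamilyError(f"unknown family {self.family!r}; "
                              f"choose from {sorted(FAMILIES)}")
        _check_domain(FAMILIES[self.family], self.params)

    @property
    def dist(self):
        fam = FAMILIES[self.family]
        return fam.frozen(**{k: self.params[k] for k in fam.param_names})

    def pdf(self, x):
        return self.dist.pdf(x)

    def cdf(self, x):
        return self.dist.cdf(x)

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return self.dist.rvs(size=n, random_state=rng)

    def support(self) -> tuple[float, float]:
        lo, hi = self.dist.support()
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricDistribution":
        return cls(d["family"], dict(d["params"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ParametricDistribution":
        return cls.from_dict(json.loads(s))


def make_distribution(family: str, params: dict) -> ParametricDistribution:
    """Validate `params` against the family domain and build a distribution."""
    return ParametricDistribution(family, dict(params))


def family_applicable(family: str, sample: np.ndarray) -> bool:
    """True if the sample lies inside the family's support."""
    return FAMILIES[family].supports(np.asarray(sample, dtype=float))


def moment_fit(sample, family: str) -> ParametricDistribution:
    """Method-of-moments fit of `family` to `sample`.

    normal: (x̄, s);  gamma: k = x̄²/s², θ = s²/x̄;  exponential: λ = 1/x̄;
    uniform: (min, max);  lognormal: moments of log(x).
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise FamilyError("moment_fit needs a 1-D sample with n >= 2")
    fam = FAMILIES.get(family)
    if fam is None:
        raise FamilyError(f"unknown family {family!r}")
    if not fam.supports(x):
        raise FamilyError(f"{family}: sample violates the family support")
    if np.var(x) == 0:
        raise FamilyError("degenerate sample: zero variance")
    return ParametricDistribution(family, fam.fit(x))


def interval_probability(d: ParametricDistribution, interval) -> float:
    """P((x_lo, x_hi]) = cdf(x_hi) − cdf(x_lo)."""
    lo, hi = float(interval[0]), float(interval[1])
    if lo >= hi:
        raise ValueError(f"reversed interval endpoints ({lo}, {hi}]")
    p = float(d.cdf(hi) - d.cdf(lo))
    return min(max(p, 0.0), 1.0)


def param_bounds(family: str) -> dict[str, tuple[float | None, float | None]]:
    """Open domain bounds per parameter name."""
    fam = FAMILIES[family]
    return dict(zip(fam.param_names, fam.bounds))


# --------------------------------------------------------------------------
# vectorized helpers used by the fuzzy divergence grid search


def batch_cdf(family: str, thetas: np.ndarray, x: np.ndarray) -> np.ndarray:
    """cdf evaluated for m parameter vectors at once.

    thetas: (m, k) array in the family's parameter order; x: (T,) points.
    Returns (m, T).
    """
    th = np.atleast_2d(np.asarray(thetas, dtype=float))
    xx = np.asarray(x, dtype=float)[None, :]
    if family == "normal":
        return stats.norm.cdf(xx, loc=th[:, :1], scale=th[:, 1:2])
    if family == "gamma":
        return stats.gamma.cdf(xx, th[:, :1], scale=th[:, 1:2])
    if family == "exponential":
        return stats.expon.cdf(xx, scale=1.0 / th[:, :1])
    if family == "uniform":
        return stats.uniform.cdf(xx, loc=th[:, :1], scale=th[:, 1:2] - th[:, :1])
    if family == "lognormal":
        return stats.lognorm.cdf(xx, th[:, 1:2], scale=np.exp(th[:, :1]))
    raise FamilyError(f"unknown family {family!r}")


def suff_stats(family: str, sample: np.ndarray) -> dict:
    """Sufficient statistics needed by `loglik_grid`."""
    x = np.asarray(sample, dtype=float)
    n = len(x)
    base = {"n": n}
    if family in ("normal",):
        base.update(sx=float(x.sum()), sxx=float((x ** 2).sum()))
    elif family == "gamma":
        base.update(sx=float(x.sum()), slogx=float(np.log(x).sum()))
    elif family == "exponential":
        base.update(sx=float(x.sum()))
    elif family == "uniform":
        base.update(xmin=float(x.min()), xmax=float(x.max()))
    elif family == "lognormal":
        lx = np.log(x)
        base.update(sx=float(lx.sum()), sxx=float((lx ** 2).sum()),
                    slogx=float(lx.sum()))
    else:
        raise FamilyError(f"unknown family {family!r}")
    return base


def loglik_grid(family: str, mesh: dict[str, np.ndarray], stats_: dict) -> np.ndarray:
    """Sample log-likelihood on a parameter mesh from sufficient statistics.

    `mesh` maps parameter names to broadcastable arrays; the return value
    has the broadcast shape.
    """
    from scipy.special import gammaln

    n = stats_["n"]
    if family == "normal":
        mu, sd = mesh["mean"], mesh["sd"]
        var = sd ** 2
        ss = stats_["sxx"] - 2 * mu * stats_["sx"] + n * mu ** 2
        return -0.5 * n * np.log(2 * np.pi * var) - ss / (2 * var)
    if family == "gamma":
        k, th = mesh["shape"], mesh["scale"]
        return ((k - 1) * stats_["slogx"] - stats_["sx"] / th
                - n * (k * np.log(th) + gammaln(k)))
    if family == "exponential":
        lam = mesh["rate"]
        return n * np.log(lam) - lam * stats_["sx"]
    if family == "uniform":
        lo, up = mesh["lower"], mesh["upper"]
        ok = (lo <= stats_["xmin"]) & (up >= stats_["xmax"]) & (up > lo)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = -n * np.log(np.where(ok, up - lo, 1.0))
        return np.where(ok, ll, -np.inf)
    if family == "lognormal":
        mu, sd = mesh["meanlog"], mesh["sdlog"]
        var = sd ** 2
        ss = stats_["sxx"] - 2 * mu * stats_["sx"] + n * mu ** 2
        return (-0.5 * n * np.log(2 * np.pi * var) - ss / (2 * var)
                - stats_["slogx"])
    raise FamilyError(f"unknown family {family!r}")
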